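import numpy as np
import pytest

from axiscope import FeatureMatrix, SpotMap, make_section


@pytest.fixture
def parallel_rows() -> SpotMap:
    """Two horizontal rows: dorsal at y=2, ventral at y=0."""
    return SpotMap(
        spot_ids=np.array(["d0", "d1", "v0", "v1"], dtype=object),
        coords=np.array([[0.0, 2.0], [1.0, 2.0], [0.0, 0.0], [1.0, 0.0]]),
        region=np.array(["dorsal", "dorsal", "ventral", "ventral"], dtype=object),
    )


@pytest.fixture
def random_spotmap():
    """Factory for random annotated point clouds with dorsal above ventral."""

    def build(n_d=20, n_v=20, n_u=10, seed=0):
        rng = np.random.default_rng(seed)
        coords = np.vstack(
            [
                rng.uniform([-1, 1.5], [1, 3], size=(n_d, 2)),
                rng.uniform([-1, -1], [1, 0.5], size=(n_v, 2)),
                rng.uniform([-1, 0.5], [1, 1.5], size=(n_u, 2)),
            ]
        )
        region = np.array(
            ["dorsal"] * n_d + ["ventral"] * n_v + ["unassigned"] * n_u,
            dtype=object,
        )
        ids = np.array([f"s{i:04d}" for i in range(len(region))], dtype=object)
        return SpotMap(spot_ids=ids, coords=coords, region=region)

    return build


@pytest.fixture(scope="session")
def default_section():
    """The default synthetic section used across recovery tests."""
    return make_section(seed=11)


def make_count_matrix(values, obs_prefix="c", gene_names=None, annotations=None):
    values = np.asarray(values, dtype=float)
    n_obs, n_genes = values.shape
    obs = np.array([f"{obs_prefix}{i}" for i in range(n_obs)], dtype=object)
    genes = (
        np.array(gene_names, dtype=object)
        if gene_names is not None
        else np.array([f"G{j}" for j in range(n_genes)], dtype=object)
    )
    return FeatureMatrix(
        obs_ids=obs, var_ids=genes, values=values, kind="counts",
        gene_annotations=annotations,
    )
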