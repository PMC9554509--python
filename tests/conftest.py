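import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lohmil.bags import Bag
from lohmil.synthetic import SimConfig, simulate_bags

# timing-based deadlines are flaky on constrained CI hardware
settings.register_profile(
    "ci", deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

CNCF_HEADER = (
    "chrom\tseg\tnum.mark\tnhet\tcnlr.median\tsegclust\tcnlr.median.clust"
    "\tstart\tend\tmafR\tmafR.clust\tcf.em\ttcn.em\tlcn.em"
)

CNCF_ROWS = [
    "1\t1\t120\t35\t-0.25\t2\t-0.21\t1000000\t5000000\t1.5\t1.4\t0.8\t2\t1",
    "2\t2\t80\t12\t0.5\t1\t0.45\t2000000\t9000000\t0.3\t0.35\t0.65\t4\t2",
    "X\t3\t60\t7\t-1.0\t3\t-0.9\t1500000\t2500000\t2.1\t2.0\t0.9\t1\t0",
]


@pytest.fixture
def cncf_file(tmp_path):
    """A 3-row cncf fixture with all 14 columns."""
    path = tmp_path / "sampleA_cncf.tsv"
    path.write_text(CNCF_HEADER + "\n" + "\n".join(CNCF_ROWS) + "\n")
    return path


@pytest.fixture
def make_cncf(tmp_path):
    """Factory writing a cncf file from a header line and row lines."""

    def _make(header, rows, name="fixture_cncf.tsv"):
        path = tmp_path / name
        path.write_text(header + "\n" + "\n".join(rows) + "\n")
        return path

    return _make


def two_cluster_bags():
    """Tiny 2-D bags with positive clusters at (0.2, 0.8) and (0.8, 0.2)."""
    a = np.array([0.2, 0.8])
    b = np.array([0.8, 0.2])
    bags = [
        Bag("p1", np.array([a + 0.01, [0.5, 0.5]]), 1),
        Bag("p2", np.array([a - 0.01, [0.45, 0.5]]), 1),
        Bag("p3", np.array([b + 0.01, [0.5, 0.45]]), 1),
        Bag("p4", np.array([b - 0.01, [0.55, 0.5]]), 1),
        Bag("n1", np.array([[0.5, 0.5], [0.45, 0.55]]), -1),
        Bag("n2", np.array([[0.55, 0.45], [0.5, 0.55]]), -1),
    ]
    return bags, np.vstack([a, b])


@pytest.fixture
def cluster2d():
    return two_cluster_bags()


@pytest.fixture(scope="session")
def sim_default():
    """The default synthetic cohort (28+28 bags, 3 planted concepts, seed 7)."""
    return simulate_bags(SimConfig())


@pytest.fixture(scope="session")
def sim_small():
    """A small, fast synthetic cohort for CV-heavy tests."""
    cfg = SimConfig(n_pos=10, n_neg=10, instances_per_bag=(3, 8), seed=11)
    return simulate_bags(cfg)


def dd_grid_search(bags, step=0.01):
    """Brute-force single-concept diverse density over a lattice on [0,1]^2.

    Independent oracle: evaluates the product of bag likelihoods at every
    lattice point and returns (best point, best DD value).
    """
    grid = np.arange(0.0, 1.0 + step / 2, step)
    best_dd, best_t = -1.0, None
    for gx in grid:
        for gy in grid:
            t = np.array([gx, gy])
            dd = 1.0
            for bag in bags:
                sims = np.exp(-((bag.instances - t) ** 2).sum(axis=1))
                m = sims.max()
                dd *= m if bag.label > 0 else 1.0 - m
            if dd > best_dd:
                best_dd, best_t = dd, t
    return best_t, best_dd
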