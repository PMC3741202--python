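import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from occunet.data import prune_correlated
from occunet.network import DispersalKernel, build_network
from occunet.occupancy import fit_balanced_ensemble
from occunet.synthetic import default_landscape


def make_labelled_patches(
    n_presence: int,
    n_absence: int,
    beta: np.ndarray | None = None,
    n_covariates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Quick surveyed patch table with i.i.d. covariates.

    With ``beta`` given (intercept first), outcomes are drawn from the
    logistic model and the class counts are whatever the draw produces of
    the requested totals; with ``beta=None`` the first ``n_presence`` rows
    are detections regardless of covariates (pure label bookkeeping).
    """
    rng = np.random.default_rng(seed)
    n = n_presence + n_absence
    X = rng.standard_normal((n, n_covariates))
    if beta is None:
        y = np.zeros(n, dtype=bool)
        y[:n_presence] = True
    else:
        p = expit(beta[0] + X @ beta[1:])
        y = rng.random(n) < p
    df = pd.DataFrame(X, columns=[f"cov{k + 1:02d}" for k in range(n_covariates)])
    df.insert(0, "patch_id", [f"P{i:04d}" for i in range(n)])
    df.insert(1, "x", rng.uniform(0, 10_000, n))
    df.insert(2, "y", rng.uniform(0, 10_000, n))
    df.insert(3, "watershed", "W00")
    df["survey_outcome"] = np.where(y, "detected", "not_detected")
    return df


def pair_network(p1: float = 0.6, p2: float = 0.8, d: float = 500.0):
    """Two patches ``d`` meters apart under the default 1 km linear kernel."""
    patches = pd.DataFrame(
        {
            "patch_id": ["A", "B"],
            "x": [0.0, d],
            "y": [0.0, 0.0],
            "watershed": ["W00", "W00"],
        }
    )
    return build_network(patches, [p1, p2], DispersalKernel())


def random_network(rng: np.random.Generator, n: int = 12):
    """Random small network: clustered coordinates, uniform intrinsic probs."""
    patches = pd.DataFrame(
        {
            "patch_id": [f"P{i}" for i in range(n)],
            "x": rng.uniform(0, 3000, n),
            "y": rng.uniform(0, 3000, n),
            "watershed": "W00",
        }
    )
    p = rng.uniform(0.01, 0.99, n)
    return build_network(patches, p, DispersalKernel())


@pytest.fixture(scope="session")
def mid_landscape() -> pd.DataFrame:
    """An 800-patch landscape under the default study conditions."""
    return default_landscape(seed=7, n_patches=800)


@pytest.fixture(scope="session")
def mid_pruned(mid_landscape):
    pruned, report = prune_correlated(mid_landscape)
    return pruned, report


@pytest.fixture(scope="session")
def mid_ensemble(mid_pruned):
    """A 20-member balanced ensemble trained on all surveyed mid patches."""
    pruned, _ = mid_pruned
    train = pruned[pruned["survey_outcome"] != "unsurveyed"]
    return train, fit_balanced_ensemble(train, n_members=20, seed=3)
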