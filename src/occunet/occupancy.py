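"""Intrinsic ("environmental quality") breeding-probability models.

Three fitting routes, in increasing order of what the analysis actually
uses:

* :func:`fit_glm` — a plain logistic GLM (binomial errors, logit link) on
  a chosen term set;
* :func:`step_aic` — greedy bidirectional (add/drop) model selection by
  AIC, starting from the full model by default;
* :func:`fit_balanced_ensemble` — the balanced-subsample ensemble: each
  of ``n_members`` (default 100) members is a stepwise-AIC GLM trained on
  *all* presence patches plus an equal-size random subsample of absence
  patches, and the ensemble prediction is the arithmetic mean over
  members.  This counters a ~7:1 absence:presence imbalance and spreads
  predicted probabilities over the full (0, 1) range.

Coefficient values are not interpreted anywhere in the package: member
models may select different terms, and predictions — not coefficients —
are the quantity carried into the network stage.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .data import covariate_columns

__all__ = [
    "FittedGLM",
    "EnsembleModel",
    "SeparationError",
    "fit_glm",
    "step_aic",
    "fit_balanced_ensemble",
    "predict",
    "outcome_to_binary",
]

#: |coefficient| beyond which a logistic fit on standardized covariates is
#: treated as (quasi-)separated rather than informative.
_SEPARATION_COEF = 40.0


class SeparationError(RuntimeError):
    """The likelihood is unbounded: a term perfectly separates the classes."""


class ConvergenceError(RuntimeError):
    pass


def outcome_to_binary(patches: pd.DataFrame) -> np.ndarray:
    """Map survey outcomes to 1 (detected) / 0 (not detected).

    Raises if any patch is unsurveyed: models are trained on surveyed
    patches only.
    """
    outcome = patches["survey_outcome"].to_numpy()
    if (outcome == "unsurveyed").any():
        raise ValueError("training data contains unsurveyed patches")
    return (outcome == "detected").astype(float)


def _design(patches: pd.DataFrame, terms: list[str]) -> np.ndarray:
    for t in terms:
        if t not in patches.columns:
            raise KeyError(f"missing covariate {t!r}")
    n = len(patches)
    X = np.empty((n, len(terms) + 1))
    X[:, 0] = 1.0
    if terms:
        X[:, 1:] = patches[list(terms)].to_numpy(dtype=float)
    return X


@dataclass
class FittedGLM:
    """A fitted logistic GLM.

    ``params`` holds the intercept first, then one coefficient per entry
    of ``selected_terms``, on the logit scale.  The AIC identity
    ``aic == -2 llf + 2 (len(selected_terms) + 1)`` always holds.
    """

    selected_terms: list[str]
    params: np.ndarray
    log_likelihood: float
    aic: float
    n_obs: int
    converged: bool = True
    bse: np.ndarray | None = None  # Wald standard errors, aligned with params

    def linear_predictor(self, patches: pd.DataFrame) -> np.ndarray:
        X = _design(patches, self.selected_terms)
        return X @ self.params

    def predict(self, patches: pd.DataFrame) -> np.ndarray:
        return expit(self.linear_predictor(patches))

    def to_dict(self) -> dict:
        return {
            "kind": "glm",
            "selected_terms": list(self.selected_terms),
            "params": [float(v) for v in self.params],
            "log_likelihood": self.log_likelihood,
            "aic": self.aic,
            "n_obs": self.n_obs,
            "converged": self.converged,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedGLM":
        return cls(
            selected_terms=list(d["selected_terms"]),
            params=np.asarray(d["params"], dtype=float),
            log_likelihood=float(d["log_likelihood"]),
            aic=float(d["aic"]),
            n_obs=int(d["n_obs"]),
            converged=bool(d.get("converged", True)),
        )


def fit_glm(patches: pd.DataFrame, terms: list[str] | None = None) -> FittedGLM:
    """Maximum-likelihood logistic GLM of detection on the given terms.

    ``terms=None`` uses every covariate column; ``terms=[]`` fits the
    intercept-only model.  Perfect separation raises
    :class:`SeparationError` naming the offending term rather than
    returning a silently shrunk fit.
    """
    if terms is None:
        terms = covariate_columns(patches)
    y = outcome_to_binary(patches)
    if y.sum() < 1 or (1 - y).sum() < 1:
        raise ValueError("training data needs at least one presence and one absence")
    X = _design(patches, list(terms))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Binomial())
        res = model.fit(maxiter=100)
    params = np.asarray(res.params, dtype=float)
    if terms:
        fitted = np.asarray(res.fittedvalues, dtype=float)
        perfect_fit = np.all((fitted > 0.5) == (y > 0.5)) and float(res.llf) > -1e-6 * len(y)
        if perfect_fit or np.abs(params[1:]).max() > _SEPARATION_COEF:
            worst = list(terms)[int(np.argmax(np.abs(params[1:])))]
            raise SeparationError(f"perfect separation on term {worst!r}")
    converged = bool(getattr(res, "converged", True))
    if not converged:
        raise ConvergenceError(f"IRLS failed to converge in {res.fit_history['iteration']} iterations")
    llf = float(res.llf)
    return FittedGLM(
        selected_terms=list(terms),
        params=params,
        log_likelihood=llf,
        aic=-2.0 * llf + 2.0 * (len(terms) + 1),
        n_obs=len(y),
        converged=converged,
        bse=np.asarray(res.bse, dtype=float),
    )


def step_aic(
    patches: pd.DataFrame,
    candidate_terms: list[str] | None = None,
    direction: str = "both",
    start: str = "full",
) -> FittedGLM:
    """Greedy bidirectional stepwise selection by AIC.

    From the start model (full model by default, ``start="null"`` for
    intercept-only), every single-term addition and deletion is evaluated
    each round and the move with the largest AIC decrease is applied;
    the search stops when no move decreases AIC.  Moves whose fit fails
    (e.g. separation on a subsample) are skipped with a warning.  Ties in
    AIC are broken lexicographically by term name for determinism.

    The returned model's AIC is never above that of the start model.
    """
    if direction != "both":
        raise ValueError("only direction='both' is supported")
    if candidate_terms is None:
        candidate_terms = covariate_columns(patches)
    if len(candidate_terms) < 1:
        raise ValueError("need at least one candidate term")
    if start not in ("full", "null"):
        raise ValueError("start must be 'full' or 'null'")

    cache: dict[frozenset, FittedGLM] = {}

    def _fit(terms: frozenset) -> FittedGLM:
        if terms not in cache:
            cache[terms] = fit_glm(patches, sorted(terms))
        return cache[terms]

    current = frozenset(candidate_terms) if start == "full" else frozenset()
    model = _fit(current)  # start-model failure propagates
    while True:
        moves: list[tuple[float, str, frozenset]] = []
        for t in sorted(current):
            trial = current - {t}
            try:
                moves.append((_fit(trial).aic, t, trial))
            except (SeparationError, ConvergenceError) as exc:
                warnings.warn(f"skipping drop of {t!r}: {exc}")
        for t in sorted(set(candidate_terms) - current):
            trial = current | {t}
            try:
                moves.append((_fit(trial).aic, t, trial))
            except (SeparationError, ConvergenceError) as exc:
                warnings.warn(f"skipping add of {t!r}: {exc}")
        if not moves:
            break
        moves.sort(key=lambda m: (m[0], m[1]))
        best_aic, _, best_set = moves[0]
        if best_aic < model.aic - 1e-10:
            current, model = best_set, _fit(best_set)
        else:
            break
    return model


@dataclass
class EnsembleModel:
    """Balanced-subsample stepwise-GLM ensemble.

    Every member is trained on all presences plus a fresh equal-size
    without-replacement absence subsample; ``member_subsample_ids`` keeps
    the absence patch ids used by each member for audit.  Prediction is
    the arithmetic mean of member predictions.
    """

    members: list[FittedGLM]
    member_subsample_ids: list[list[str]]
    n_members: int
    seed: int | None = None
    candidate_terms: list[str] = field(default_factory=list)

    def predict(self, patches: pd.DataFrame) -> np.ndarray:
        preds = np.stack([m.predict(patches) for m in self.members])
        return preds.mean(axis=0)

    def mean_absence_inclusion(self) -> float:
        """Average number of members each distinct absence patch appears in."""
        counts: dict[str, int] = {}
        for ids in self.member_subsample_ids:
            for pid in ids:
                counts[pid] = counts.get(pid, 0) + 1
        return float(np.mean(list(counts.values())))

    def to_dict(self) -> dict:
        return {
            "kind": "ensemble",
            "n_members": self.n_members,
            "seed": self.seed,
            "candidate_terms": list(self.candidate_terms),
            "members": [m.to_dict() for m in self.members],
            "member_subsample_ids": self.member_subsample_ids,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnsembleModel":
        return cls(
            members=[FittedGLM.from_dict(m) for m in d["members"]],
            member_subsample_ids=[list(ids) for ids in d["member_subsample_ids"]],
            n_members=int(d["n_members"]),
            seed=d.get("seed"),
            candidate_terms=list(d.get("candidate_terms", [])),
        )


def fit_balanced_ensemble(
    patches: pd.DataFrame,
    candidate_terms: list[str] | None = None,
    n_members: int = 100,
    seed: int | None = None,
) -> EnsembleModel:
    """Fit the balanced-subsample stepwise-GLM ensemble.

    With p presences and a >= p absences, the expected per-absence
    inclusion count across members is ``n_members * p / a`` (~16 for a
    154-presence / 988-absence training set with 100 members).
    """
    if candidate_terms is None:
        candidate_terms = covariate_columns(patches)
    y = outcome_to_binary(patches)
    pres = patches[y == 1]
    absn = patches[y == 0]
    if len(pres) > len(absn):
        raise ValueError(
            f"{len(pres)} presences exceed {len(absn)} absences; balanced "
            "subsampling is pointless — fit step_aic on the full data instead"
        )
    rng = np.random.default_rng(seed)
    members: list[FittedGLM] = []
    subsample_ids: list[list[str]] = []
    for _ in range(n_members):
        take = rng.choice(len(absn), size=len(pres), replace=False)
        member_train = pd.concat([pres, absn.iloc[np.sort(take)]])
        members.append(step_aic(member_train, candidate_terms))
        subsample_ids.append(absn["patch_id"].iloc[np.sort(take)].tolist())
    return EnsembleModel(
        members=members,
        member_subsample_ids=subsample_ids,
        n_members=n_members,
        seed=seed,
        candidate_terms=list(candidate_terms),
    )


def predict(model, patches: pd.DataFrame) -> np.ndarray:
    """Per-patch intrinsic breeding probability P_i from a fitted model."""
    p = model.predict(patches)
    # GLM predictions are in (0,1) analytically; guard the float boundary
    # so downstream products and NNI headroom stay well defined.
    return np.clip(p, 1e-12, 1.0 - 1e-12)


def save_model(model, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=1)


def load_model(path):
    with open(path) as fh:
        d = json.load(fh)
    if d.get("kind") == "ensemble":
        return EnsembleModel.from_dict(d)
    return FittedGLM.from_dict(d)
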