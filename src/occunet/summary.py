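"""Watershed-scale aggregation and per-patch report assembly."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .network import BoostResult, InfluenceTable, classify_quadrants

__all__ = ["summarize_watersheds", "assemble_report"]


def summarize_watersheds(
    patches: pd.DataFrame,
    p_env,
    boost: BoostResult,
    threshold: float,
) -> pd.DataFrame:
    """Per-watershed summary of environmental and network quality.

    One row per watershed with the patch count, mean intrinsic
    probability, its coefficient of variation (sample sd / mean; reported
    missing when a watershed has fewer than two patches or zero mean),
    mean NNI, and the fraction of patches whose *boosted* probability is
    strictly above ``threshold``.  Watersheds where mean probability is
    high and its CV low mark clustered hotspots.
    """
    ws = patches["watershed"]
    if ws.isna().any() or (ws.astype(str) == "").any():
        bad = patches.loc[ws.isna() | (ws.astype(str) == ""), "patch_id"].tolist()
        raise ValueError(f"patches without watershed label: {bad[:10]}")
    df = pd.DataFrame(
        {
            "watershed": ws.to_numpy(),
            "p_env": np.asarray(p_env, dtype=float),
            "p_total": boost.p_total,
            "nni": boost.nni,
        }
    )
    rows = []
    for w, grp in df.groupby("watershed", sort=True):
        mean_p = float(grp["p_env"].mean())
        if len(grp) < 2 or mean_p == 0.0:
            cv = np.nan
        else:
            cv = float(grp["p_env"].std(ddof=1) / mean_p)
        rows.append(
            {
                "watershed": w,
                "n_patches": len(grp),
                "mean_p_env": mean_p,
                "cv_p_env": cv,
                "mean_nni": float(grp["nni"].mean()),
                "pct_predicted_breeding": float((grp["p_total"] > threshold).mean()),
            }
        )
    return pd.DataFrame(rows)


def assemble_report(
    patches: pd.DataFrame,
    p_env,
    boost: BoostResult,
    influence: InfluenceTable,
    env_threshold: float,
    nni_threshold: float = 0.5,
) -> pd.DataFrame:
    """Master per-patch table joining every stage of the analysis.

    Columns: id/coordinates/watershed/survey outcome, intrinsic and
    boosted probabilities, NNI, deletion influence G, quadrant label, and
    a flag for patches whose G exceeds the 90th percentile of deletion
    influence among patches with observed breeding (the high-impact
    known-breeding subset most relevant to management).  All inputs must
    cover exactly the same patch ids.
    """
    ids = patches["patch_id"].to_numpy()
    for name, other in (("boost", boost.patch_ids), ("influence", influence.patch_ids)):
        if len(other) != len(ids) or set(other) != set(ids):
            raise ValueError(
                f"patch_id mismatch with {name} result: "
                f"{len(ids)} patches vs {len(other)} entries"
            )
    report = patches[
        [c for c in ("patch_id", "x", "y", "watershed", "survey_outcome") if c in patches]
    ].copy()
    report["p_env"] = np.asarray(p_env, dtype=float)
    boost_df = boost.to_frame().set_index("patch_id")
    infl_df = influence.to_frame().set_index("patch_id")
    report = report.join(boost_df[["p_total", "nni"]], on="patch_id")
    report = report.join(infl_df[["g"]], on="patch_id")
    report["quadrant"] = classify_quadrants(
        report["p_env"], report["nni"], env_threshold, nni_threshold
    )
    if "survey_outcome" in report:
        detected_g = report.loc[report["survey_outcome"] == "detected", "g"]
    else:
        detected_g = pd.Series(dtype=float)
    if len(detected_g):
        q90 = float(np.quantile(detected_g, 0.9))
        report["top_decile_influence"] = report["g"] > q90
    else:
        report["top_decile_influence"] = False
    return report
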