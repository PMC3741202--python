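"""Patch tables: schema, file I/O, and covariate preparation.

A *patch table* is a :class:`pandas.DataFrame` with one row per habitat
patch.  Required columns are ``patch_id`` (unique string), projected
coordinates ``x``/``y`` in meters, and a ``watershed`` label.  A
``survey_outcome`` column, when present, takes exactly one of the values
``detected``, ``not_detected`` or ``unsurveyed``.  Every other numeric
column that is not in :data:`RESERVED_COLUMNS` is treated as an
environmental covariate.

Coordinates are assumed to be planar meters in a projected CRS; the
package never reprojects them (all dispersal distances downstream are
metric, with a hard 1 km default cutoff).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Columns with a fixed meaning; everything else numeric is a covariate.
RESERVED_COLUMNS = (
    "patch_id",
    "x",
    "y",
    "watershed",
    "survey_outcome",
    "true_prob",
    "true_breeding",
)

#: Legal survey outcomes, in the CSV/GeoJSON representation.
OUTCOMES = ("detected", "not_detected", "unsurveyed")

REQUIRED_COLUMNS = ("patch_id", "x", "y", "watershed")


class SchemaError(ValueError):
    """A patch table violates the required schema."""


def validate_patch_table(patches: pd.DataFrame) -> None:
    """Raise :class:`SchemaError` if ``patches`` is not a valid patch table."""
    for col in REQUIRED_COLUMNS:
        if col not in patches.columns:
            raise SchemaError(f"patch table is missing required column {col!r}")
    if patches["patch_id"].duplicated().any():
        dupes = patches.loc[patches["patch_id"].duplicated(), "patch_id"].tolist()
        raise SchemaError(f"duplicate patch_id values: {dupes[:5]}")
    xy = patches[["x", "y"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(xy)):
        raise SchemaError("non-finite coordinates in patch table")
    if "survey_outcome" in patches.columns:
        bad = set(patches["survey_outcome"].unique()) - set(OUTCOMES)
        if bad:
            raise SchemaError(f"unknown survey_outcome values: {sorted(bad)}")


def covariate_columns(patches: pd.DataFrame) -> list[str]:
    """Names of covariate columns, in table order."""
    return [
        c
        for c in patches.columns
        if c not in RESERVED_COLUMNS
        and pd.api.types.is_numeric_dtype(patches[c])
    ]


def read_patch_table(path, dialect: str | None = None) -> pd.DataFrame:
    """Read a patch table from CSV or a GeoJSON FeatureCollection of Points.

    Parameters
    ----------
    path
        File to read.
    dialect
        ``"csv"`` or ``"geojson"``; inferred from the file extension when
        omitted.

    Rows are preserved in file order and unknown extra columns are carried
    through untouched.
    """
    path = str(path)
    if dialect is None:
        dialect = "geojson" if path.endswith((".geojson", ".json")) else "csv"
    if dialect == "csv":
        df = pd.read_csv(path, dtype={"patch_id": str})
    elif dialect == "geojson":
        with open(path) as fh:
            fc = json.load(fh)
        rows = []
        for feat in fc["features"]:
            props = dict(feat.get("properties") or {})
            geom = feat.get("geometry") or {}
            if geom.get("type") == "Point":
                props.setdefault("x", geom["coordinates"][0])
                props.setdefault("y", geom["coordinates"][1])
            rows.append(props)
        df = pd.DataFrame(rows)
        if "patch_id" in df.columns:
            df["patch_id"] = df["patch_id"].astype(str)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    validate_patch_table(df)
    return df


def write_patch_table(patches: pd.DataFrame, path, dialect: str | None = None) -> None:
    """Write a patch table as CSV or a GeoJSON FeatureCollection of Points."""
    path = str(path)
    if dialect is None:
        dialect = "geojson" if path.endswith((".geojson", ".json")) else "csv"
    if dialect == "csv":
        patches.to_csv(path, index=False)
    elif dialect == "geojson":
        features = []
        for _, row in patches.iterrows():
            props = {
                k: (v.item() if isinstance(v, np.generic) else v)
                for k, v in row.items()
            }
            features.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "Point",
                        "coordinates": [float(row["x"]), float(row["y"])],
                    },
                    "properties": props,
                }
            )
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


@dataclass
class CovariateReport:
    """Record of covariate pruning decisions.

    ``correlation_pairs`` holds ``(kept_name, dropped_name, r)`` triples for
    every pair whose absolute Pearson correlation exceeded the threshold;
    ``zero_variance`` lists constant columns dropped because their
    correlation with anything is undefined.
    """

    kept: list[str] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)
    correlation_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    zero_variance: list[str] = field(default_factory=list)
    threshold: float = 0.9

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"kept": a, "dropped": b, "r": r, "reason": "correlated"}
            for a, b, r in self.correlation_pairs
        ]
        rows += [
            {"kept": "", "dropped": c, "r": np.nan, "reason": "zero variance"}
            for c in self.zero_variance
        ]
        return pd.DataFrame(rows, columns=["kept", "dropped", "r", "reason"])

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def prune_correlated(
    patches: pd.DataFrame,
    threshold: float = 0.9,
    columns: list[str] | None = None,
) -> tuple[pd.DataFrame, CovariateReport]:
    """Drop covariates that are highly correlated with an earlier one.

    Scans covariate columns greedily in table order (or in the order given
    by ``columns``): a column is dropped if its absolute Pearson correlation
    with any already-kept column exceeds ``threshold``.  Constant columns,
    for which the correlation is undefined, are dropped with reason
    "zero variance".  The operation is idempotent.

    Returns the table with dropped columns removed and a
    :class:`CovariateReport` listing every decision.
    """
    cols = columns if columns is not None else covariate_columns(patches)
    if len(cols) < 2:
        raise ValueError("need at least 2 covariate columns to prune")
    X = patches[cols].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("covariates contain missing values; imputation is not supported")
    report = CovariateReport(threshold=threshold)
    kept_idx: list[int] = []
    for j, col in enumerate(cols):
        if np.std(X[:, j]) == 0.0:
            report.dropped.append(col)
            report.zero_variance.append(col)
            continue
        offending = []
        for i in kept_idx:
            r = float(np.corrcoef(X[:, i], X[:, j])[0, 1])
            if abs(r) > threshold:
                offending.append((cols[i], col, r))
        if offending:
            report.dropped.append(col)
            report.correlation_pairs.extend(offending)
        else:
            kept_idx.append(j)
            report.kept.append(col)
    pruned = patches.drop(columns=report.dropped)
    return pruned, report


def split_train_test(
    patches: pd.DataFrame,
    n_test_presence: int,
    n_test_absence: int,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hold out a test set with fixed class counts from the surveyed patches.

    The test set contains exactly ``n_test_presence`` patches with detected
    breeding and ``n_test_absence`` surveyed patches without, sampled
    without replacement; the training set is every other surveyed patch.
    Unsurveyed patches appear in neither.
    """
    if "survey_outcome" not in patches.columns:
        raise SchemaError("patch table has no survey_outcome column")
    surveyed = patches[patches["survey_outcome"] != "unsurveyed"]
    pres = surveyed[surveyed["survey_outcome"] == "detected"]
    absn = surveyed[surveyed["survey_outcome"] == "not_detected"]
    if n_test_presence > len(pres) or n_test_absence > len(absn):
        raise ValueError(
            f"requested test counts (presence={n_test_presence}, "
            f"absence={n_test_absence}) exceed available "
            f"(presence={len(pres)}, absence={len(absn)})"
        )
    rng = np.random.default_rng(seed)
    test_idx = np.concatenate(
        [
            rng.choice(pres.index.to_numpy(), size=n_test_presence, replace=False),
            rng.choice(absn.index.to_numpy(), size=n_test_absence, replace=False),
        ]
    )
    test = surveyed.loc[np.sort(test_idx)]
    train = surveyed.drop(index=test_idx)
    return train, test
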