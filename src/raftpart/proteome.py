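"""Proteome-scale batch prediction and compartment-wise comparison.

``batch_predict`` scores every record it can and collects the rest into a
rejects table with reasons, so a noisy proteome-scale input never aborts
the run. ``compare_compartments`` then contrasts the raft-relevant features
(predicted dG, ASA, TMD length, palmitoylation) between subcellular
compartments with per-group descriptive statistics and a one-way ANOVA
per quantity. By default ER and Golgi are pooled into a single
intracellular comparator group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import ModelParams, predict
from .palmitoylation import PalmConfig
from .physchem import ResidueScale
from .seqio import TMDRecord

logger = logging.getLogger(__name__)

#: Quantities contrasted between compartments.
COMPARED_QUANTITIES = ("dG_pred", "asa", "tmd_len_res", "n_palm")

PREDICTION_COLUMNS = [
    "id", "asa", "n_palm", "d_tmd", "tmd_len_res",
    "asa_term", "palm_term", "mismatch_term", "dG_pred", "kp_pred", "compartment",
]


def batch_predict(
    records: Sequence[TMDRecord],
    params: ModelParams,
    scale: ResidueScale | None = None,
    palm_config: PalmConfig = PalmConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score a record collection; returns (predictions, rejects).

    One prediction row per scoreable record; records that cannot be scored
    (scale gaps, invalid spans carried with ``validate=False``, ...) land
    in the rejects table with the reason. Row counts always satisfy
    ``len(predictions) + len(rejects) == len(records)``.
    """
    if len(records) == 0:
        raise ValueError("batch_predict requires at least one record")
    rows, rejects = [], []
    for rec in records:
        try:
            p = predict(rec, params, scale=scale, palm_config=palm_config)
        except Exception as exc:
            rejects.append(dict(id=rec.id, reason=str(exc)))
            continue
        rows.append(
            dict(
                id=p.record_id,
                asa=p.asa,
                n_palm=p.n_palm,
                d_tmd=p.d_tmd,
                tmd_len_res=rec.tmd_len,
                asa_term=p.asa_term,
                palm_term=p.palm_term,
                mismatch_term=p.mismatch_term,
                dG_pred=p.dG_pred,
                kp_pred=p.kp_pred,
                compartment=rec.compartment,
            )
        )
    predictions = pd.DataFrame(rows, columns=PREDICTION_COLUMNS)
    rejects_df = pd.DataFrame(rejects, columns=["id", "reason"])
    if not rejects_df.empty:
        logger.warning("%d record(s) rejected during batch prediction", len(rejects_df))
    return predictions, rejects_df


@dataclass(frozen=True)
class ComparisonReport:
    """Compartment comparison: group stats plus one-way ANOVA per quantity.

    ``anova`` is None when fewer than two usable groups remain (the report
    degrades to descriptive statistics).
    """

    group_stats: pd.DataFrame  # index: (group, quantity); columns: n, mean, sd
    anova: pd.DataFrame | None  # index: quantity; columns: F, p
    groups: dict[str, int]  # group label -> n
    excluded: tuple[str, ...]  # groups dropped for insufficient n


def compare_compartments(
    predictions: pd.DataFrame,
    pool_er_golgi: bool = True,
    min_n: int = 3,
    outlier_abs_dG: float | None = None,
) -> ComparisonReport:
    """Contrast raft-relevant features across compartment groups.

    ``pool_er_golgi`` merges ER and Golgi labels into one "ER/Golgi"
    comparator (the documented default). ``outlier_abs_dG``, if given,
    excludes rows with |dG_pred| beyond the bound (logged) before any
    statistics — off by default. Groups below ``min_n`` are excluded with
    a warning. The result is invariant to row order.
    """
    df = predictions.dropna(subset=["compartment"]).copy()
    if df.empty:
        raise ValueError("no rows with a compartment label")
    if outlier_abs_dG is not None:
        before = len(df)
        df = df[df["dG_pred"].abs() <= outlier_abs_dG]
        if len(df) < before:
            logger.info("excluded %d outlier row(s) with |dG_pred| > %g",
                        before - len(df), outlier_abs_dG)
    if pool_er_golgi:
        df["compartment"] = df["compartment"].replace({"ER": "ER/Golgi", "Golgi": "ER/Golgi"})

    counts = df["compartment"].value_counts()
    excluded = tuple(sorted(counts[counts < min_n].index))
    for grp in excluded:
        logger.warning("group %r excluded: n=%d < %d", grp, counts[grp], min_n)
    df = df[~df["compartment"].isin(excluded)]
    if df.empty:
        raise ValueError("all groups below the minimum group size")

    stats_rows = []
    for grp in sorted(df["compartment"].unique()):
        sub = df[df["compartment"] == grp]
        for qty in COMPARED_QUANTITIES:
            vals = sub[qty].to_numpy(dtype=float)
            stats_rows.append(
                dict(group=grp, quantity=qty, n=len(vals), mean=float(np.mean(vals)),
                     sd=float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0)
            )
    group_stats = pd.DataFrame(stats_rows).set_index(["group", "quantity"]).sort_index()

    groups = {g: int(counts[g]) for g in sorted(df["compartment"].unique())}
    anova = None
    if len(groups) >= 2:
        rows = []
        for qty in COMPARED_QUANTITIES:
            samples = [
                df.loc[df["compartment"] == g, qty].to_numpy(dtype=float) for g in groups
            ]
            f, p = stats.f_oneway(*samples)
            rows.append(dict(quantity=qty, F=float(f), p=float(p)))
        anova = pd.DataFrame(rows).set_index("quantity")
    return ComparisonReport(group_stats=group_stats, anova=anova, groups=groups, excluded=excluded)


def write_predictions(
    predictions: pd.DataFrame,
    path: str | Path,
    params: ModelParams | None = None,
) -> None:
    """Write predictions as TSV, echoing the parameter set as '#' headers."""
    with open(path, "w") as fh:
        if params is not None:
            for key in ("delta_gamma", "dG_palm", "B_LP", "d_lo", "d_ld", "temperature", "dG_ex"):
                fh.write(f"# {key} = {getattr(params, key)!r}\n")
        predictions.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_predictions(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
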