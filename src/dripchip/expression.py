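"""RNase-H-overexpression expression arm.

Inputs are summarized expression signals per transcript and sample (long
format: id, sample, condition in {control, treatment}, replicate, signal,
detection_p). Arrays are scaled to a common median target intensity; a
transcript is kept when it is reliably detected (detection p <= 0.05 and
signal >= 100 in every sample) and its treatment/control fold change
exceeds 2 (strictly) in either direction. The up/down sets are then
characterized against the annotation: antisense association by Fisher's
exact test, GC content and transcriptional frequency by Wilcoxon rank-sum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Collection

import numpy as np
import pandas as pd

from .stats import (
    AssociationResult,
    association_report,
    set_association,
    wilcoxon_rank_sum,
)

logger = logging.getLogger(__name__)

EXPRESSION_COLUMNS = ("id", "sample", "condition", "replicate", "signal",
                      "detection_p")


def read_expression_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "sample": str})
    missing = [c for c in EXPRESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"expression table missing columns: {missing}")
    bad = set(df["condition"].unique()) - {"control", "treatment"}
    if bad:
        raise ValueError(f"unknown condition labels: {sorted(bad)}")
    return df


def write_expression_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def median_scale(records: pd.DataFrame, target: float = 500.0) -> pd.DataFrame:
    """Scale each sample's signal vector so its median equals ``target``."""
    out = records.copy()
    for sample, grp in records.groupby("sample"):
        med = float(grp["signal"].median())
        if med <= 0:
            raise ValueError(f"sample {sample}: non-positive median signal")
        out.loc[grp.index, "signal"] = grp["signal"] * (target / med)
    return out


@dataclass
class ModulationResult:
    up: list[str]
    down: list[str]
    table: pd.DataFrame = field(repr=False)


def filter_modulated(
    records: pd.DataFrame,
    p_cut: float = 0.05,
    signal_min: float = 100.0,
    fold: float = 2.0,
    log_scale: bool = False,
) -> ModulationResult:
    """Select transcripts modulated by the treatment.

    A transcript passes detection iff ``detection_p <= p_cut`` and
    ``signal >= signal_min`` in *every* sample. Fold change is the ratio of
    condition means (geometric means with ``log_scale=True``); upregulated
    iff FC > fold, downregulated iff FC < 1/fold, both strict, so a
    transcript at exactly 2-fold is excluded. Transcripts with zero control
    mean are excluded and logged.
    """
    up: list[str] = []
    down: list[str] = []
    rows = []
    dropped_zero = 0
    for tid, grp in records.groupby("id", sort=True):
        detected = bool(
            (grp["detection_p"] <= p_cut).all()
            and (grp["signal"] >= signal_min).all()
        )
        treat = grp.loc[grp["condition"] == "treatment", "signal"].to_numpy(float)
        ctrl = grp.loc[grp["condition"] == "control", "signal"].to_numpy(float)
        if len(treat) == 0 or len(ctrl) == 0:
            raise ValueError(f"{tid}: needs samples in both conditions")
        if log_scale:
            if np.any(treat <= 0) or np.any(ctrl <= 0):
                fc = float("nan")
            else:
                fc = float(np.exp(np.log(treat).mean() - np.log(ctrl).mean()))
        else:
            cmean = ctrl.mean()
            fc = treat.mean() / cmean if cmean > 0 else float("nan")
        status = "unchanged"
        if not detected:
            status = "not_detected"
        elif not np.isfinite(fc):
            status = "undefined_fc"
            dropped_zero += 1
        elif fc > fold:
            status = "up"
            up.append(str(tid))
        elif fc < 1.0 / fold:
            status = "down"
            down.append(str(tid))
        rows.append({"id": tid, "detected": detected, "fold_change": fc,
                     "status": status})
    if dropped_zero:
        logger.info("%d transcripts had zero control mean; excluded", dropped_zero)
    return ModulationResult(sorted(up), sorted(down),
                            pd.DataFrame(rows).set_index("id"))


def modulated_set_characterization(
    up_ids: Collection[str],
    down_ids: Collection[str],
    annotations: pd.DataFrame,
    universe_ids: Collection[str] | None = None,
) -> pd.DataFrame:
    """Consolidated report on the up/down sets.

    Antisense association via Fisher's exact test against the universe
    (default: every transcript with an annotation record); GC content and
    transcriptional frequency via Wilcoxon rank-sum of the set against the
    rest of the universe. Empty sets are reported as not applicable.
    """
    universe = set(universe_ids) if universe_ids is not None else set(
        annotations.index
    )
    antisense = set(annotations.index[annotations["antisense"]]) & universe
    rows = []
    for label, ids in (("up", set(up_ids)), ("down", set(down_ids))):
        ids &= universe
        if not ids:
            rows.append({"set": label, "analysis": "antisense_fisher",
                         "n": 0, "statistic": np.nan, "p": np.nan,
                         "note": "empty set"})
            continue
        assoc: AssociationResult = set_association(ids, universe, antisense)
        rows.append({"set": label, "analysis": "antisense_fisher",
                     "n": len(ids), "statistic": assoc.odds_ratio,
                     "p": assoc.p_value,
                     "note": f"{assoc.percent_annotated:.1f}% antisense"})
        rest = universe - ids
        for attr in ("gc_fraction", "txn_frequency"):
            xv = annotations.loc[sorted(ids), attr].dropna().to_numpy()
            yv = annotations.loc[sorted(rest), attr].dropna().to_numpy()
            if len(xv) == 0 or len(yv) == 0:
                continue
            u, p = wilcoxon_rank_sum(xv, yv, mode="normal-approx")
            rows.append({"set": label, "analysis": f"{attr}_wilcoxon",
                         "n": len(ids), "statistic": u, "p": p,
                         "note": f"set mean {xv.mean():.3g} vs rest {yv.mean():.3g}"})
    return pd.DataFrame(rows)


def antisense_overlap_report(
    enriched_ids: Collection[str],
    modulated_ids: Collection[str],
    antisense_ids: Collection[str],
    universe_ids: Collection[str],
) -> pd.DataFrame:
    """Antisense-association percentages of the hybrid-enriched set, the
    expression-modulated set, and their intersection, each with its Fisher
    p against the universe. Mirrors the overlap summary of the published
    gene lists when fed those lists."""
    enriched = set(enriched_ids)
    modulated = set(modulated_ids)
    results = {
        "hybrid_enriched": set_association(enriched, universe_ids, antisense_ids),
        "rnaseh_modulated": set_association(modulated, universe_ids, antisense_ids),
        "enriched_and_modulated": set_association(
            enriched & modulated, universe_ids, antisense_ids
        ),
    }
    return association_report(results)
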