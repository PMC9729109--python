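"""Post-authentication abundance, sample-depth and replicate filtering.

After damage authentication, taxonomic profiles are cleaned in four stages:

1. drop taxa whose damage fit fails the authentication thresholds
   (D_max and lambda_LR), or that have no fit at all;
2. drop taxa whose dataset-wide read total does not strictly exceed the
   median taxon total divided by ``median_divisor`` (low-abundance taxa);
3. drop samples whose read total does not strictly exceed the median sample
   total divided by ``median_divisor`` (shallow samples);
4. drop taxa detected in fewer than ``min_replicates`` distinct samples.

Medians are recomputed over the retained set at each stage. Finally counts
are normalized to within-sample proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .damage import AuthThresholds, DamageFit, classify_authentic
from .lca import TaxonProfile


@dataclass
class FilterConfig:
    """Cascade thresholds; stage order is fixed (damage, taxon median,
    sample median, replicates) and medians recompute after each stage."""

    dmax_min: float = 0.25
    lr_min: float = 1.5
    median_divisor: float = 2.0
    min_replicates: int = 3

    def __post_init__(self) -> None:
        if min(self.dmax_min, self.lr_min, self.median_divisor) < 0 or self.min_replicates < 0:
            raise ValueError("all filter thresholds must be nonnegative")


def apply_filters(
    profile: TaxonProfile,
    fits: dict[int, DamageFit] | None,
    config: FilterConfig | None = None,
) -> tuple[TaxonProfile, pd.DataFrame]:
    """Run the four-stage cascade; returns the filtered profile and a log
    with one row per removed taxon or sample naming the triggering rule.

    Pass ``fits=None`` to skip the damage stage (e.g. when filtering a
    profile authenticated upstream).
    """
    config = config or FilterConfig()
    counts = profile.counts.copy()
    log_rows: list[dict] = []

    # stage 1: damage authentication per taxon
    if fits is not None:
        th = AuthThresholds(dmax_min=config.dmax_min, lr_min=config.lr_min)
        bad = []
        for node in counts["node"].unique():
            fit = fits.get(node)
            if fit is None or not classify_authentic(fit, th):
                bad.append(node)
                log_rows.append(
                    {
                        "stage": "damage",
                        "kind": "taxon",
                        "id": node,
                        "rule": (
                            "no damage fit"
                            if fit is None
                            else f"D_max={fit.d_max:.3f}, lambda_LR={fit.lambda_lr:.3f} "
                            f"below ({config.dmax_min}, {config.lr_min})"
                        ),
                    }
                )
        counts = counts[~counts["node"].isin(bad)]

    # stage 2: taxon totals vs median/divisor (strict >)
    if len(counts):
        totals = counts.groupby("node")["count"].sum()
        threshold = float(np.median(totals.values)) / config.median_divisor
        bad = totals.index[totals <= threshold].tolist()
        for node in bad:
            log_rows.append(
                {
                    "stage": "taxon_median",
                    "kind": "taxon",
                    "id": node,
                    "rule": f"total {totals[node]} <= median/{config.median_divisor:g} = {threshold:g}",
                }
            )
        counts = counts[~counts["node"].isin(bad)]

    # stage 3: sample totals vs median/divisor (strict >)
    if len(counts):
        stotals = counts.groupby("sample")["count"].sum()
        threshold = float(np.median(stotals.values)) / config.median_divisor
        bad_samples = stotals.index[stotals <= threshold].tolist()
        for s in bad_samples:
            log_rows.append(
                {
                    "stage": "sample_median",
                    "kind": "sample",
                    "id": s,
                    "rule": f"total {stotals[s]} <= median/{config.median_divisor:g} = {threshold:g}",
                }
            )
        counts = counts[~counts["sample"].isin(bad_samples)]

    # stage 4: replicate support (distinct samples with the taxon present)
    if len(counts):
        support = counts[counts["count"] > 0].groupby("node")["sample"].nunique()
        bad = support.index[support < config.min_replicates].tolist()
        for node in bad:
            log_rows.append(
                {
                    "stage": "replicates",
                    "kind": "taxon",
                    "id": node,
                    "rule": f"detected in {support[node]} < {config.min_replicates} replicates",
                }
            )
        counts = counts[~counts["node"].isin(bad)]

    filtered = TaxonProfile(
        counts=counts.reset_index(drop=True),
        metadata=profile.metadata,
        unassigned=profile.unassigned,
    )
    log = pd.DataFrame(log_rows, columns=["stage", "kind", "id", "rule"])
    return filtered, log


def normalize_proportions(profile: TaxonProfile) -> pd.DataFrame:
    """Within-sample proportions of the retained taxa (sum to 1 per sample).

    Raises
    ------
    ValueError
        Naming the sample, if any retained sample has zero total reads.
    """
    counts = profile.counts
    out = counts.copy()
    totals = counts.groupby("sample")["count"].transform("sum")
    zero = counts.loc[totals == 0, "sample"].unique()
    if len(zero):
        raise ValueError(f"zero-total sample(s): {', '.join(map(str, zero))}")
    out["proportion"] = counts["count"] / totals
    return out[["sample", "node", "count", "proportion"]]
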