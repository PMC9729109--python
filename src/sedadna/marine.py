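"""Marine reference-genome validation statistics.

Reads classified near the root are re-mapped against marine eukaryotic
reference genomes (SMAGs); a genome is only trusted when its mapping looks
genuinely genome-wide rather than driven by a few conserved islands:

* **mean read ANI** — average nucleotide identity of mapped reads (%),
  with the working cutoff picked at the elbow of the reads-vs-ANI curve;
* **breadth ratio** — observed fraction of positions covered, divided by the
  Poisson expectation 1 - exp(-mean depth) for random placement (capped at 1);
* **evenness** — E = (1/floor(d)) * sum_{i=1..floor(d)} F_i where F_i is the
  fraction of positions with depth >= i and d the mean depth (E = F_1 when
  d < 1); 1 for perfectly uniform coverage;

combined with the damage-authentication statistics (D_max, lambda_LR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .damage import DamageFit


@dataclass
class MarineMapStats:
    """Per-genome mapping summary used by the retention filter."""

    genome: str
    reads_mapped: int
    mean_ani_pct: float
    mean_depth: float
    breadth: float
    expected_breadth: float
    breadth_ratio: float
    evenness: float
    flagged: bool = False  # zero mapped reads

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def coverage_depth(
    starts: np.ndarray, ends: np.ndarray, genome_length: int
) -> np.ndarray:
    """Per-position depth from half-open [start, end) intervals (0-based)."""
    delta = np.zeros(genome_length + 1, dtype=np.int64)
    np.add.at(delta, np.clip(starts, 0, genome_length), 1)
    np.add.at(delta, np.clip(ends, 0, genome_length), -1)
    return np.cumsum(delta[:-1])


def coverage_evenness(depth: np.ndarray) -> float:
    """E = (1/floor(d)) * sum_{i<=floor(d)} frac(depth >= i); F_1 when d < 1."""
    d_bar = float(depth.mean())
    if d_bar == 0:
        return 0.0
    top = max(1, int(np.floor(d_bar)))
    levels = np.arange(1, top + 1)
    frac_ge = np.array([(depth >= i).mean() for i in levels])
    return float(frac_ge.mean())


def reference_map_stats(
    alignments: pd.DataFrame, genome: str, genome_length: int
) -> MarineMapStats:
    """Compute mapping statistics for one genome.

    ``alignments`` needs columns (read, genome, start, end, ani) with
    half-open 0-based coordinates and per-read ANI as a percentage.
    Duplicate fragments (identical start/end/strand, or start/end when no
    strand column is present) are collapsed first, mirroring duplicate
    marking in the mapping workflow.
    """
    if genome_length <= 0:
        raise ValueError("genome length must be positive")
    sub = alignments[alignments["genome"] == genome]
    dedup_cols = ["start", "end"] + (["strand"] if "strand" in sub.columns else [])
    sub = sub.drop_duplicates(subset=dedup_cols)
    n = len(sub)
    if n == 0:
        return MarineMapStats(genome, 0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, flagged=True)
    depth = coverage_depth(
        sub["start"].to_numpy(), sub["end"].to_numpy(), genome_length
    )
    mean_depth = float(depth.mean())
    breadth = float((depth > 0).mean())
    expected = float(1.0 - np.exp(-mean_depth))
    ratio = min(breadth / expected, 1.0) if expected > 0 else 0.0
    return MarineMapStats(
        genome=genome,
        reads_mapped=int(n),
        mean_ani_pct=float(sub["ani"].mean()),
        mean_depth=mean_depth,
        breadth=breadth,
        expected_breadth=expected,
        breadth_ratio=ratio,
        evenness=coverage_evenness(depth),
    )


def ani_elbow(cutoffs: np.ndarray, reads_retained: np.ndarray) -> float:
    """Elbow of the reads-retained-vs-ANI-cutoff curve.

    Returns the cutoff maximizing perpendicular distance to the chord joining
    the curve's endpoints, ties broken toward the lower cutoff. Needs at
    least three points with ascending cutoffs.
    """
    x = np.asarray(cutoffs, dtype=float)
    y = np.asarray(reads_retained, dtype=float)
    if len(x) < 3:
        raise ValueError("elbow detection needs at least 3 curve points")
    if np.any(np.diff(x) <= 0):
        raise ValueError("cutoffs must be strictly ascending")
    # normalize both axes so the chord distance is scale-free
    xs = (x - x[0]) / (x[-1] - x[0])
    ys = (y - y[0]) / (y[-1] - y[0]) if y[-1] != y[0] else np.zeros_like(y)
    # distance from (xs, ys) to the line through (0,0) and (1,1)
    dist = np.abs(xs - ys) / np.sqrt(2.0)
    interior = slice(1, len(x) - 1)
    best = 1 + int(np.argmax(dist[interior]))
    return float(x[best])


@dataclass
class MarineThresholds:
    """Retention cutoffs; reads/ANI/breadth/evenness/D_max are inclusive
    (>=), lambda_LR is strict (>)."""

    min_reads: int = 500
    min_ani_pct: float = 93.0
    min_breadth_ratio: float = 0.75
    min_evenness: float = 0.75
    dmax_min: float = 0.25
    lr_min: float = 1.5


def select_genomes(
    stats: list[MarineMapStats],
    fits: dict[str, DamageFit],
    thresholds: MarineThresholds | None = None,
) -> pd.DataFrame:
    """Apply the retention filter to per-genome stats + damage fits.

    Returns one row per genome with the decision and, when removed, the
    first triggering rule.
    """
    th = thresholds or MarineThresholds()
    rows = []
    for s in stats:
        fit = fits.get(s.genome)
        rule = ""
        if s.reads_mapped < th.min_reads:
            rule = f"reads_mapped {s.reads_mapped} < {th.min_reads}"
        elif s.mean_ani_pct < th.min_ani_pct:
            rule = f"mean_ani {s.mean_ani_pct:.2f}% < {th.min_ani_pct}%"
        elif s.breadth_ratio < th.min_breadth_ratio:
            rule = f"breadth_ratio {s.breadth_ratio:.3f} < {th.min_breadth_ratio}"
        elif s.evenness < th.min_evenness:
            rule = f"evenness {s.evenness:.3f} < {th.min_evenness}"
        elif fit is None:
            rule = "no damage fit"
        elif fit.d_max < th.dmax_min:
            rule = f"D_max {fit.d_max:.3f} < {th.dmax_min}"
        elif not fit.lambda_lr > th.lr_min:
            rule = f"lambda_LR {fit.lambda_lr:.3f} <= {th.lr_min}"
        rows.append(
            {
                **s.to_dict(),
                "d_max": fit.d_max if fit else np.nan,
                "lambda_lr": fit.lambda_lr if fit else np.nan,
                "retained": rule == "",
                "rule": rule,
            }
        )
    return pd.DataFrame(rows)
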