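"""Postmortem DNA-damage estimation and authentication.

Cytosine deamination in ancient fragments shows up as C->T substitutions
concentrated at the 5' terminus (and complementary G->A at the 3' terminus).
Per taxonomic node we tally, at each of the first K positions from either
end, the number of reads with a reference C (G) there — the opportunities —
and how many of those were read as T (A). The damage model says the
substitution frequency at 1-based terminal position x is

    f(x) = A * (1 - q)**(x - 1) + c

(excess terminal damage A decaying geometrically by q over background c),
fitted by maximum likelihood under a beta-binomial with concentration phi to
absorb between-read overdispersion. The null model is a constant frequency.
Two statistics authenticate a node:

* ``D_max = A + c`` — the fitted damage frequency at position 1;
* ``lambda_LR = 2 * (loglik_damage - loglik_null)`` — how decisively the
  decaying model beats the constant-rate null.

A node is called ancient when D_max >= 0.25 and lambda_LR >= 1.5 (defaults).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import betaln, gammaln

from .lca import decode_mismatches
from .taxonomy import Taxonomy


@dataclass
class DamageCounts:
    """Positional substitution tallies for one node: k = observed C->T
    (G->A) counts, n = opportunities, indexed by terminal distance 1..K."""

    k5: np.ndarray
    n5: np.ndarray
    k3: np.ndarray
    n3: np.ndarray
    n_reads: int = 0

    @classmethod
    def zeros(cls, k_positions: int) -> "DamageCounts":
        z = lambda: np.zeros(k_positions, dtype=np.int64)
        return cls(z(), z(), z(), z(), 0)

    def __iadd__(self, other: "DamageCounts") -> "DamageCounts":
        self.k5 += other.k5
        self.n5 += other.n5
        self.k3 += other.k3
        self.n3 += other.n3
        self.n_reads += other.n_reads
        return self

    def frequencies(self) -> tuple[np.ndarray, np.ndarray]:
        """(5' C->T, 3' G->A) empirical frequencies with 0/0 -> 0."""
        with np.errstate(invalid="ignore"):
            f5 = np.where(self.n5 > 0, self.k5 / np.maximum(self.n5, 1), 0.0)
            f3 = np.where(self.n3 > 0, self.k3 / np.maximum(self.n3, 1), 0.0)
        return f5, f3


class MismatchMatrix:
    """Per-node positional damage tallies with subtree aggregation."""

    def __init__(self, k_positions: int = 15):
        if k_positions < 2:
            raise ValueError("need at least 2 terminal positions")
        self.k_positions = k_positions
        self.counts: dict[int, DamageCounts] = {}

    def node(self, node: int) -> DamageCounts:
        if node not in self.counts:
            self.counts[node] = DamageCounts.zeros(self.k_positions)
        return self.counts[node]

    def add_read(self, node: int, read: str, mismatches: list[tuple[int, str, str]]) -> None:
        """Count one aligned read at *node*.

        The aligned reference is the read with the mismatch substitutions
        reverted, so opportunities are exact."""
        acc = self.node(node)
        count_read_terminals(read, mismatches, acc)

    def aggregated(self, taxonomy: Taxonomy) -> "MismatchMatrix":
        """New matrix where each node also includes all subtree reads."""
        out = MismatchMatrix(self.k_positions)
        for node, c in self.counts.items():
            acc = out.node(node)
            acc += c
        for node in taxonomy.postorder():
            parent = taxonomy.parent[node]
            if parent != node and node in out.counts:
                parent_acc = out.node(parent)
                parent_acc += out.counts[node]
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for node, c in sorted(self.counts.items()):
            for x in range(self.k_positions):
                rows.append(
                    {
                        "node": node,
                        "position": x + 1,
                        "k5": c.k5[x],
                        "n5": c.n5[x],
                        "k3": c.k3[x],
                        "n3": c.n3[x],
                    }
                )
        return pd.DataFrame(rows)


def count_read_terminals(
    read: str, mismatches: list[tuple[int, str, str]], acc: DamageCounts
) -> None:
    """Tally one read's first/last K positions into *acc* (in place)."""
    k_pos = len(acc.k5)
    length = len(read)
    ref = list(read)
    for p, refb, _ in mismatches:
        ref[p - 1] = refb
    kk = min(k_pos, length)
    for x in range(kk):
        if ref[x] == "C":
            acc.n5[x] += 1
            if read[x] == "T":
                acc.k5[x] += 1
        j = length - 1 - x
        if ref[j] == "G":
            acc.n3[x] += 1
            if read[j] == "A":
                acc.k3[x] += 1
    acc.n_reads += 1


def tally_mismatches(
    hits: pd.DataFrame,
    reads: dict[str, str],
    assignments: pd.DataFrame,
    taxonomy: Taxonomy,
    k_positions: int = 15,
) -> MismatchMatrix:
    """Build the per-node mismatch matrix from assigned reads.

    Each assigned read contributes through its best (highest-identity) hit's
    mismatch list; counts at a node include all subtree reads.
    """
    matrix = MismatchMatrix(k_positions)
    assigned = assignments[assignments["node"] != -1]
    node_of = dict(zip(assigned["read_id"], assigned["node"]))
    best = hits.loc[hits.groupby("read_id")["identity"].idxmax()]
    for rec in best.itertuples(index=False):
        node = node_of.get(rec.read_id)
        if node is None:
            continue
        matrix.add_read(node, reads[rec.read_id], decode_mismatches(rec.mismatches))
    return matrix.aggregated(taxonomy)


@dataclass
class DamageFit:
    """Maximum-likelihood damage estimate for one node."""

    a: float
    q: float
    c: float
    phi: float
    d_max: float
    lambda_lr: float
    n_reads: int
    loglik: float = 0.0
    loglik_null: float = 0.0
    null_c: float = 0.0

    def to_dict(self) -> dict:
        return {
            "A": self.a,
            "q": self.q,
            "c": self.c,
            "phi": self.phi,
            "D_max": self.d_max,
            "lambda_LR": self.lambda_lr,
            "n_reads": self.n_reads,
        }


def _betabinom_loglik(k: np.ndarray, n: np.ndarray, f: np.ndarray, phi: float) -> float:
    f = np.clip(f, 1e-9, 1 - 1e-9)
    a = f * phi
    b = (1.0 - f) * phi
    ll = (
        gammaln(n + 1)
        - gammaln(k + 1)
        - gammaln(n - k + 1)
        + betaln(k + a, n - k + b)
        - betaln(a, b)
    )
    return float(np.sum(ll))

_PHI_BOUNDS = (np.log(1.0), np.log(1e7))


def fit_damage(counts: DamageCounts) -> DamageFit:
    """Fit the decaying-damage model and the constant-rate null to one node.

    Both models use beta-binomial likelihoods with a free concentration phi;
    the null is the A = 0 submodel, so the likelihood-ratio statistic
    2 * (l_damage - l_null) is nonnegative up to optimizer tolerance.
    Optimization is bounded L-BFGS-B from five deterministic starts.

    Raises
    ------
    ValueError
        If there are no opportunities at any position (undefined fit).
    """
    x = np.arange(1, len(counts.k5) + 1, dtype=float)
    pos = np.concatenate([x, x])
    k = np.concatenate([counts.k5, counts.k3]).astype(float)
    n = np.concatenate([counts.n5, counts.n3]).astype(float)
    use = n > 0
    if not np.any(use):
        raise ValueError("undefined fit: no substitution opportunities")
    pos, k, n = pos[use], k[use], n[use]

    def nll_alt(theta: np.ndarray) -> float:
        a, q, c, logphi = theta
        f = a * (1.0 - q) ** (pos - 1.0) + c
        return -_betabinom_loglik(k, n, f, np.exp(logphi))

    def nll_null(theta: np.ndarray) -> float:
        c, logphi = theta
        return -_betabinom_loglik(k, n, np.full_like(pos, c), np.exp(logphi))

    # background start: frequency in the interior (positions past the decay)
    tail = pos > np.median(pos)
    c0 = float(np.clip(k[tail].sum() / max(n[tail].sum(), 1.0), 1e-4, 0.4))
    head0 = float(np.clip(k[pos == 1].sum() / max(n[pos == 1].sum(), 1.0), 1e-4, 0.98))

    best_null = None
    for c_start in (c0, 0.01, 0.1):
        res = minimize(
            nll_null,
            x0=[c_start, np.log(1e3)],
            method="L-BFGS-B",
            bounds=[(1e-6, 0.999), _PHI_BOUNDS],
        )
        if best_null is None or res.fun < best_null.fun:
            best_null = res

    starts = [
        (max(head0 - c0, 1e-3), 0.3, c0),
        (0.05, 0.3, c0),
        (0.3, 0.5, c0),
        (0.6, 0.2, 0.01),
        (1e-3, 0.3, head0),
    ]
    best_alt = None
    for a0, q0, cc0 in starts:
        res = minimize(
            nll_alt,
            x0=[a0, q0, cc0, np.log(1e3)],
            method="L-BFGS-B",
            bounds=[(0.0, 0.999), (1e-3, 0.999), (1e-6, 0.999), _PHI_BOUNDS],
        )
        if best_alt is None or res.fun < best_alt.fun:
            best_alt = res

    ll_alt, ll_null = -best_alt.fun, -best_null.fun
    a, q, c, logphi = best_alt.x
    lam = max(0.0, 2.0 * (ll_alt - ll_null))
    return DamageFit(
        a=float(a),
        q=float(q),
        c=float(c),
        phi=float(np.exp(logphi)),
        d_max=float(min(a + c, 1.0)),
        lambda_lr=float(lam),
        n_reads=counts.n_reads,
        loglik=ll_alt,
        loglik_null=ll_null,
        null_c=float(best_null.x[0]),
    )


def fit_all_nodes(matrix: MismatchMatrix, min_reads: int = 1) -> dict[int, DamageFit]:
    """Fit every node in a (subtree-aggregated) mismatch matrix with at
    least *min_reads* reads and a nonzero opportunity total."""
    fits: dict[int, DamageFit] = {}
    for node, counts in matrix.counts.items():
        if counts.n_reads < min_reads or counts.n5.sum() + counts.n3.sum() == 0:
            continue
        fits[node] = fit_damage(counts)
    return fits


@dataclass
class AuthThresholds:
    """Authentication cutoffs: minimum terminal damage and likelihood ratio."""

    dmax_min: float = 0.25
    lr_min: float = 1.5


def classify_authentic(fit: DamageFit, thresholds: AuthThresholds | None = None) -> bool:
    """True iff the node passes both damage-authentication thresholds
    (D_max >= 0.25 and lambda_LR >= 1.5 by default, both inclusive)."""
    th = thresholds or AuthThresholds()
    if not (np.isfinite(fit.d_max) and np.isfinite(fit.lambda_lr)):
        raise ValueError("damage fit is not finite")
    return fit.d_max >= th.dmax_min and fit.lambda_lr >= th.lr_min


def fits_to_frame(fits: dict[int, DamageFit], taxonomy: Taxonomy | None = None) -> pd.DataFrame:
    rows = []
    for node, fit in sorted(fits.items()):
        row = {"node": node, **fit.to_dict()}
        if taxonomy is not None:
            row["rank"] = taxonomy.rank.get(node, "")
            row["name"] = taxonomy.name.get(node, "")
        rows.append(row)
    return pd.DataFrame(rows)
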