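"""Synthetic inputs for the whole pipeline.

Generates a small reference taxonomy with divergence-controlled reference
sequences, ancient-style reads carrying geometrically decaying terminal
deamination (C->T from the 5' end, G->A from the 3' end) over a constant
background mismatch rate, competitive hit tables consistent with those reads,
and geochronology inputs (Al-26/Be-10 pairs decayed from a known burial age,
piecewise temperature histories). Everything is seeded and byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .geochron import BurialConfig, TemperatureHistory
from .lca import HIT_COLUMNS, encode_mismatches
from .taxonomy import Taxonomy

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = (ord(b) for b in "ACGT")


@dataclass
class DamageParams:
    """Positional deamination model: excess terminal damage ``a`` decaying
    per position by ``q``, on top of background mismatch rate ``c``.
    The C->T probability at 1-based 5' position x is a*(1-q)**(x-1) + c."""

    a: float = 0.40
    q: float = 0.30
    c: float = 0.01

    def __post_init__(self) -> None:
        if not (0 <= self.a and 0 <= self.c <= 1 and self.a + self.c <= 1):
            raise ValueError(f"require a >= 0, 0 <= c <= 1, a + c <= 1; got {self}")
        if not (0 < self.q < 1):
            raise ValueError(f"decay q must be in (0, 1); got {self.q}")

    def rate(self, position: np.ndarray | int) -> np.ndarray:
        """Damage probability at 1-based terminal distance *position*."""
        return self.a * (1.0 - self.q) ** (np.asarray(position) - 1) + self.c


@dataclass
class SimulationConfig:
    """Study-condition knobs for read simulation.

    ``taxon_abundances`` maps species node id -> relative weight of the
    ancient (damaged) community; ``contaminant_abundances`` optionally gives
    a different composition for the modern (undamaged) contaminant fraction,
    defaulting to the ancient one.
    """

    taxon_abundances: dict[int, float] = field(default_factory=dict)
    damage: DamageParams = field(default_factory=DamageParams)
    fragment_mean: float = 50.0
    fragment_dispersion: float = 0.35
    fragment_min: int = 30
    fragment_max: int = 150
    contamination_fraction: float = 0.0
    contaminant_abundances: dict[int, float] | None = None
    n_reads: int = 10_000
    n_replicates: int = 1
    n_sites: int = 1
    n_units: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.array(list(self.taxon_abundances.values()), dtype=float)
        if len(w) and (w.min() < 0 or w.max() <= 0):
            raise ValueError("abundances must be nonnegative with at least one positive")
        if not (0.0 <= self.contamination_fraction <= 1.0):
            raise ValueError("contamination_fraction must lie in [0, 1]")
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")


def make_taxonomy_and_refs(
    n_genera: int,
    species_per_genus: int,
    ref_length: int,
    seed: int,
    sibling_divergence: float = 0.03,
    genus_divergence: float = 0.10,
    genera_per_family: int = 2,
) -> tuple[Taxonomy, dict[int, str]]:
    """Build a root->family->genus->species taxonomy and one reference
    sequence per species.

    Species references are produced by substituting a controlled proportion
    of sites of their genus ancestor (half of ``sibling_divergence`` each, so
    sibling pairs differ at roughly ``sibling_divergence`` of sites); no
    indels, so all references share coordinates within a genus.
    """
    if n_genera < 1 or species_per_genus < 1:
        raise ValueError("n_genera and species_per_genus must be >= 1")
    if ref_length < 100:
        raise ValueError("ref_length must be >= 100")
    rng = np.random.default_rng(seed)
    tax = Taxonomy()
    root = 1
    tax.add_node(root, root, "no rank", "root")

    refs: dict[int, str] = {}
    n_families = (n_genera + genera_per_family - 1) // genera_per_family
    for f in range(n_families):
        fam = 10 + f
        tax.add_node(fam, root, "family", f"family_{f + 1}")
    for g in range(n_genera):
        genus = 100 + g
        fam = 10 + g // genera_per_family
        tax.add_node(genus, fam, "genus", f"genus_{g + 1}")
        ancestor = rng.choice(_BASES, size=ref_length)
        # genus ancestors drift apart; exact proportion is immaterial
        _mutate(ancestor, int(round(genus_divergence * ref_length)), rng)
        for s in range(species_per_genus):
            sp = 1000 + g * species_per_genus + s
            tax.add_node(sp, genus, "species", f"species_{g + 1}_{s + 1}")
            seq = ancestor.copy()
            _mutate(seq, int(round(sibling_divergence / 2 * ref_length)), rng)
            refs[sp] = seq.tobytes().decode()
    tax.validate()
    return tax, refs


def _mutate(seq: np.ndarray, n_sites: int, rng: np.random.Generator) -> None:
    """Substitute *n_sites* distinct random positions in place."""
    if n_sites == 0:
        return
    pos = rng.choice(len(seq), size=n_sites, replace=False)
    shift = rng.integers(1, 4, size=n_sites)
    idx = np.searchsorted(_BASES, seq[pos])
    seq[pos] = _BASES[(idx + shift) % 4]


def _truncated_lognormal_mu(mean: float, sigma: float, lo: float, hi: float) -> float:
    """Location parameter so the [lo, hi]-truncated lognormal has the
    requested mean (closed-form partial expectation, solved by bisection)."""

    def trunc_mean(mu: float) -> float:
        a = (np.log(lo) - mu) / sigma
        b = (np.log(hi) - mu) / sigma
        mass = norm.cdf(b) - norm.cdf(a)
        partial = np.exp(mu + sigma**2 / 2) * (
            norm.cdf(b - sigma) - norm.cdf(a - sigma)
        )
        return partial / mass

    return brentq(lambda m: trunc_mean(m) - mean, np.log(lo) - 2, np.log(hi) + 2)


def _sample_ids(config: SimulationConfig) -> tuple[list[str], dict[str, dict]]:
    samples, meta = [], {}
    for site in range(1, config.n_sites + 1):
        for unit in range(1, config.n_units + 1):
            for rep in range(1, config.n_replicates + 1):
                sid = f"S{site}.U{unit}.R{rep}"
                samples.append(sid)
                meta[sid] = {
                    "site": f"site_{site}",
                    "unit": f"unit_{unit}",
                    "layer": f"layer_{unit}",
                    "replicate": rep,
                }
    return samples, meta


def simulate_reads(
    refs: dict[int, str], config: SimulationConfig
) -> tuple[dict[str, str], pd.DataFrame, dict[str, dict]]:
    """Draw fragments from the references and inject terminal deamination.

    Ancient reads get C->T substitutions at 5' position x with probability
    a*(1-q)**(x-1) + c (on cytosines) and mirrored G->A from the 3' end;
    contaminant reads see only the background rate c on both substitution
    types. Fragment lengths follow a lognormal truncated to
    [fragment_min, fragment_max] whose truncated mean equals fragment_mean.

    Returns (reads, truth_table, sample_metadata); the truth table records
    per read its source taxon, sample, damaged flag, reference start and the
    injected substitution positions.
    """
    if not refs:
        raise ValueError("refs must be nonempty")
    abund = config.taxon_abundances or {sp: 1.0 for sp in refs}
    for sp in abund:
        if sp not in refs:
            raise ValueError(f"abundance given for unknown species {sp}")
    rng = np.random.default_rng(config.seed)
    n = config.n_reads
    dmg = config.damage

    contaminant = rng.random(n) < config.contamination_fraction
    cont_abund = config.contaminant_abundances or abund

    def draw_taxa(weights: dict[int, float], size: int) -> np.ndarray:
        keys = np.array(sorted(weights))
        w = np.array([weights[k] for k in keys], dtype=float)
        return keys[rng.choice(len(keys), size=size, p=w / w.sum())]

    taxa = np.empty(n, dtype=int)
    n_cont = int(contaminant.sum())
    taxa[~contaminant] = draw_taxa(abund, n - n_cont)
    if n_cont:
        taxa[contaminant] = draw_taxa(cont_abund, n_cont)

    lo, hi = config.fragment_min, config.fragment_max
    mu = _truncated_lognormal_mu(config.fragment_mean, config.fragment_dispersion, lo, hi)
    lengths = np.empty(n, dtype=int)
    todo = np.arange(n)
    while len(todo):  # rejection-sample the truncation
        draw = np.exp(rng.normal(mu, config.fragment_dispersion, size=len(todo)))
        ok = (draw >= lo) & (draw <= hi)
        lengths[todo[ok]] = np.round(draw[ok]).astype(int)
        todo = todo[~ok]
    lengths = np.clip(lengths, lo, hi)

    ref_arrays = {sp: np.frombuffer(seq.encode(), dtype=np.uint8) for sp, seq in refs.items()}
    ref_lens = {sp: len(a) for sp, a in ref_arrays.items()}
    starts = np.array(
        [rng.integers(0, ref_lens[t] - L + 1) for t, L in zip(taxa, lengths)]
    )

    # concatenate all fragments for vectorized damage injection
    total = int(lengths.sum())
    flat = np.empty(total, dtype=np.uint8)
    offsets = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    for i in range(n):
        flat[offsets[i] : offsets[i] + lengths[i]] = ref_arrays[taxa[i]][
            starts[i] : starts[i] + lengths[i]
        ]

    rep_len = np.repeat(lengths, lengths)
    x5 = np.arange(total) - np.repeat(offsets, lengths) + 1  # 1-based from 5'
    x3 = rep_len - x5 + 1  # 1-based from 3'
    damaged_pos = np.repeat(~contaminant, lengths)
    p_ct = np.where(damaged_pos, dmg.rate(x5), dmg.c)
    p_ga = np.where(damaged_pos, dmg.rate(x3), dmg.c)
    u = rng.random(total)
    hit_ct = (flat == _C) & (u < p_ct)
    hit_ga = (flat == _G) & (u < p_ga)
    flat[hit_ct] = _T
    flat[hit_ga] = _A

    samples, meta = _sample_ids(config)
    sample_of = np.array(samples)[rng.integers(0, len(samples), size=n)]

    reads: dict[str, str] = {}
    mism_strings: list[str] = []
    changed = hit_ct | hit_ga
    for i in range(n):
        sl = slice(offsets[i], offsets[i] + lengths[i])
        rid = f"read_{i:06d}"
        reads[rid] = flat[sl].tobytes().decode()
        pos = np.nonzero(changed[sl])[0]
        ref_seq = ref_arrays[taxa[i]]
        mms = [
            (int(p) + 1, chr(ref_seq[starts[i] + p]), reads[rid][p]) for p in pos
        ]
        mism_strings.append(encode_mismatches(mms))

    truth = pd.DataFrame(
        {
            "read_id": list(reads),
            "sample": sample_of,
            "taxon": taxa,
            "damaged": ~contaminant,
            "length": lengths,
            "ref_start": starts,
            "injected": mism_strings,
        }
    )
    return reads, truth, meta


def write_fastq(reads: dict[str, str], path) -> None:
    """Emit reads as phred-33 FASTQ (uniform Q40; qualities are not modelled)."""
    with open(path, "w") as fh:
        for rid, seq in reads.items():
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")}


def simulate_hit_table(
    reads: dict[str, str],
    truth: pd.DataFrame,
    refs: dict[int, str],
    taxonomy: Taxonomy,
    identity_noise: float = 0.0,
    seed: int = 0,
    min_identity: float = 0.88,
) -> pd.DataFrame:
    """Competitive hits for each read against its source species and all
    congeneric siblings (shared coordinates, substitution-only divergence).

    Identity is 1 - mismatches/length; optional Gaussian ``identity_noise``
    perturbs the identity column only, leaving the per-position mismatch
    lists faithful to the emitted read bases. Hits below ``min_identity``
    are dropped (they could never enter the assignment window).
    """
    rng = np.random.default_rng(seed)
    ref_arrays = {sp: np.frombuffer(s.encode(), dtype=np.uint8) for sp, s in refs.items()}
    siblings: dict[int, list[int]] = {}
    for sp in refs:
        genus = taxonomy.parent[sp]
        siblings.setdefault(genus, []).append(sp)

    rows = []
    for rec in truth.itertuples(index=False):
        if rec.read_id not in reads:
            raise ValueError(f"unknown read {rec.read_id}")
        read = np.frombuffer(reads[rec.read_id].encode(), dtype=np.uint8)
        L = len(read)
        start = rec.ref_start
        genus = taxonomy.parent[rec.taxon]
        for sp in siblings[genus]:
            ref = ref_arrays[sp][start : start + L]
            diff = np.nonzero(read != ref)[0]
            identity = 1.0 - len(diff) / L
            if identity < min_identity:
                continue
            mms = [(int(p) + 1, chr(ref[p]), chr(read[p])) for p in diff]
            if identity_noise > 0:
                identity = float(np.clip(identity + rng.normal(0, identity_noise), 0, 1))
            rows.append(
                {
                    "read_id": rec.read_id,
                    "sample": rec.sample,
                    "node": sp,
                    "identity": identity,
                    "length": L,
                    "strand": "+",
                    "mismatches": encode_mismatches(mms),
                }
            )
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def simulate_geochron_inputs(
    true_age: float,
    r0: float = 6.75,
    noise_cv: float = 0.05,
    n_samples: int = 3,
    seed: int = 0,
    n10_scale: float = 1.0e5,
    temperature_spec: dict | None = None,
    burial: BurialConfig | None = None,
) -> tuple[pd.DataFrame, TemperatureHistory]:
    """Isotope pairs decayed from a known burial age, plus a temperature history.

    Each sample's true Al-26/Be-10 ratio is r0*exp(-t*(lam26-lam10)); measured
    concentrations are normally perturbed with coefficient of variation
    ``noise_cv`` and reported with 1-sigma uncertainties noise_cv*value.

    ``temperature_spec`` is either ``{"kind": "constant", "mat_c": -17.0}`` or
    ``{"kind": "glacial_cycles", "present_mat_c": ..., "glacial_cooling_c": ...,
    "period_yr": ..., "glacial_fraction": ..., "duration_yr": ...}``.
    """
    if true_age < 0:
        raise ValueError("true_age must be nonnegative")
    if r0 <= 0 or noise_cv < 0:
        raise ValueError("r0 must be positive and noise_cv nonnegative")
    burial = burial or BurialConfig(r0=r0)
    rng = np.random.default_rng(seed)
    ratio = r0 * np.exp(-true_age * (burial.lam26 - burial.lam10))
    rows = []
    for i in range(n_samples):
        n10 = n10_scale * (1.0 + 0.25 * i)  # depth-profile-like spread
        n26 = n10 * ratio
        m10 = n10 * (1.0 + noise_cv * rng.standard_normal()) if noise_cv else n10
        m26 = n26 * (1.0 + noise_cv * rng.standard_normal()) if noise_cv else n26
        rows.append(
            {
                "sample": f"GC{i + 1:02d}",
                "n10": max(m10, 1e-9 * n10_scale),
                "n10_sigma": noise_cv * n10,
                "n26": max(m26, 1e-9 * n10_scale),
                "n26_sigma": noise_cv * n26,
                "depth_m": 3.0 + 2.0 * i,
            }
        )
    pairs = pd.DataFrame(rows)

    spec = temperature_spec or {"kind": "constant", "mat_c": -17.0}
    history = make_temperature_history(spec)
    return pairs, history


def make_temperature_history(spec: dict) -> TemperatureHistory:
    """Build a piecewise temperature history from a small declarative spec."""
    kind = spec.get("kind", "constant")
    if kind == "constant":
        t_k = 273.15 + spec.get("mat_c", -17.0)
        duration = spec.get("duration_yr", 4.0e6)
        return TemperatureHistory(
            times_yr=np.array([0.0, duration]),
            temps_k=np.array([t_k, t_k]),
            interpolation="previous",
        )
    if kind == "glacial_cycles":
        present = 273.15 + spec["present_mat_c"]
        cold = present - spec["glacial_cooling_c"]
        period = spec.get("period_yr", 100_000.0)
        frac = spec.get("glacial_fraction", 0.5)
        duration = spec.get("duration_yr", 4.0e6)
        times, temps = [0.0], [present]
        t = 0.0
        while t < duration:
            warm_end = t + (1 - frac) * period
            cold_end = t + period
            times += [warm_end, cold_end]
            temps += [cold, present]
            t = cold_end
        return TemperatureHistory(
            times_yr=np.array(times), temps_k=np.array(temps), interpolation="previous"
        )
    raise ValueError(f"unknown temperature history kind {kind!r}")
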