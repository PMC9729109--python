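"""Similarity-windowed LCA read assignment and taxonomic profiling.

Each read arrives with a set of competitive alignment hits. Hits whose
nucleotide identity falls inside an absolute similarity window (default
95-100%) are kept; the read is assigned to the lowest common ancestor of the
kept hits' taxa. Reads with no accepted hit are tallied as unassigned.
Profiles count reads per node and per subtree (a node plus all descendants).
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .taxonomy import Taxonomy, lca_of_set

#: columns of the TSV hit-table dialect
HIT_COLUMNS = ["read_id", "sample", "node", "identity", "length", "strand", "mismatches"]


@dataclass
class AlignmentHit:
    """One competitive alignment of a read against one reference taxon.

    ``mismatches`` holds (position, ref_base, read_base) triples with 1-based
    positions counted from the 5' end of the read *as sequenced*; for
    reverse-strand alignments the bases are already complemented into that
    frame, so downstream damage counting never needs the genome strand.
    """

    read_id: str
    node: int
    identity: float
    length: int
    strand: str = "+"
    mismatches: list[tuple[int, str, str]] = field(default_factory=list)
    sample: str = ""


def encode_mismatches(mms: list[tuple[int, str, str]]) -> str:
    return ";".join(f"{p}:{r}:{a}" for p, r, a in mms) if mms else "."


def decode_mismatches(text: str) -> list[tuple[int, str, str]]:
    if not text or text == ".":
        return []
    out = []
    for item in text.split(";"):
        p, r, a = item.split(":")
        out.append((int(p), r, a))
    return out


def hits_to_frame(hits: list[AlignmentHit]) -> pd.DataFrame:
    """Pack hits into the TSV-dialect DataFrame."""
    return pd.DataFrame(
        {
            "read_id": [h.read_id for h in hits],
            "sample": [h.sample for h in hits],
            "node": [h.node for h in hits],
            "identity": [h.identity for h in hits],
            "length": [h.length for h in hits],
            "strand": [h.strand for h in hits],
            "mismatches": [encode_mismatches(h.mismatches) for h in hits],
        }
    )


def read_hit_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample": str, "read_id": str})
    missing = set(HIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    return df


def write_hit_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def read_sam_hits(path, taxonomy_of_reference, sample: str = "") -> pd.DataFrame:
    """Parse a SAM file (NM/MD tags required) into the hit-table dialect.

    ``taxonomy_of_reference`` maps reference names to taxonomy node ids.
    Alignments containing indels are rejected with a warning: identity is
    defined on mismatches only and the simulator emits none.
    Reverse-strand alignments are converted into the read-as-sequenced frame
    (positions flipped, bases complemented).
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            if any(op in (1, 2) for op, _ in (aln.cigartuples or [])):
                warnings.warn(
                    f"skipping alignment with indels for read {aln.query_name}",
                    stacklevel=2,
                )
                continue
            length = aln.query_length
            mms: list[tuple[int, str, str]] = []
            for qpos, _, refbase in aln.get_aligned_pairs(with_seq=True):
                if qpos is None or refbase is None:
                    continue
                qbase = aln.query_sequence[qpos]
                if refbase.islower():  # pysam lowercases mismatching ref bases
                    mms.append((qpos + 1, refbase.upper(), qbase))
            strand = "-" if aln.is_reverse else "+"
            if aln.is_reverse:
                mms = [
                    (length - p + 1, r.translate(_COMPLEMENT), a.translate(_COMPLEMENT))
                    for p, r, a in mms
                ]
                mms.sort()
            nm = len(mms)
            rows.append(
                {
                    "read_id": aln.query_name,
                    "sample": sample,
                    "node": taxonomy_of_reference[aln.reference_name],
                    "identity": 1.0 - nm / length,
                    "length": length,
                    "strand": strand,
                    "mismatches": encode_mismatches(mms),
                }
            )
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


@dataclass
class AssignConfig:
    """Read-assignment parameters: the absolute similarity window and the
    minimum read length (bp) for a hit to be considered."""

    similarity_lo: float = 0.95
    similarity_hi: float = 1.00
    min_length: int = 30

    def __post_init__(self) -> None:
        if not (0.0 <= self.similarity_lo <= self.similarity_hi <= 1.0):
            raise ValueError(
                f"invalid similarity window [{self.similarity_lo}, {self.similarity_hi}]"
            )


@dataclass
class TaxonProfile:
    """Per-sample read counts per taxonomic node, with replicate structure.

    ``counts``: DataFrame (sample, node, count) of direct assignments.
    ``metadata``: sample id -> dict with site/unit/layer/replicate keys.
    ``unassigned``: sample id -> number of reads with no accepted hit.
    """

    counts: pd.DataFrame
    metadata: dict[str, dict] = field(default_factory=dict)
    unassigned: dict[str, int] = field(default_factory=dict)

    def total_assigned(self, sample: str) -> int:
        sub = self.counts[self.counts["sample"] == sample]
        return int(sub["count"].sum())

    def subtree_counts(self, taxonomy: Taxonomy) -> pd.DataFrame:
        """Counts aggregated over each node's subtree, per sample."""
        out = []
        for sample, sub in self.counts.groupby("sample"):
            direct = dict(zip(sub["node"], sub["count"]))
            agg = dict(direct)
            for node in taxonomy.postorder():
                parent = taxonomy.parent[node]
                if parent != node and node in agg:
                    agg[parent] = agg.get(parent, 0) + agg[node]
            for node, c in sorted(agg.items()):
                out.append(
                    {
                        "sample": sample,
                        "node": node,
                        "count": direct.get(node, 0),
                        "subtree_count": c,
                    }
                )
        return pd.DataFrame(out, columns=["sample", "node", "count", "subtree_count"])

    def write(self, path, taxonomy: Taxonomy) -> None:
        df = self.subtree_counts(taxonomy)
        df["rank"] = df["node"].map(taxonomy.rank)
        df["name"] = df["node"].map(taxonomy.name)
        df[["sample", "node", "rank", "name", "count", "subtree_count"]].to_csv(
            path, sep="\t", index=False
        )


def assign_reads(
    hits: pd.DataFrame, taxonomy: Taxonomy, config: AssignConfig | None = None
) -> pd.DataFrame:
    """Assign each read to the LCA of its accepted hits.

    Returns a DataFrame (read_id, sample, node) with node == -1 for reads
    whose hits all fall outside the similarity window or below the minimum
    length.
    """
    config = config or AssignConfig()
    ok = (
        (hits["identity"] >= config.similarity_lo - 1e-12)
        & (hits["identity"] <= config.similarity_hi + 1e-12)
        & (hits["length"] >= config.min_length)
    )
    accepted = hits[ok]
    rows = []
    seen = set()
    for (read_id, sample), sub in accepted.groupby(["read_id", "sample"], sort=False):
        node = lca_of_set(taxonomy, set(sub["node"]))
        rows.append({"read_id": read_id, "sample": sample, "node": node})
        seen.add((read_id, sample))
    for (read_id, sample), _ in hits.groupby(["read_id", "sample"], sort=False):
        if (read_id, sample) not in seen:
            rows.append({"read_id": read_id, "sample": sample, "node": -1})
    return pd.DataFrame(rows, columns=["read_id", "sample", "node"])


def assign_and_profile(
    hits: pd.DataFrame,
    taxonomy: Taxonomy,
    config: AssignConfig | None = None,
    metadata: dict[str, dict] | None = None,
) -> TaxonProfile:
    """Windowed-LCA assignment followed by per-sample profiling.

    Unassigned reads (no hit inside the window) are tallied separately so
    that assigned + unassigned equals the number of reads per sample.
    """
    assignments = assign_reads(hits, taxonomy, config)
    assigned = assignments[assignments["node"] != -1]
    counts = (
        assigned.groupby(["sample", "node"]).size().reset_index(name="count")
        if len(assigned)
        else pd.DataFrame(columns=["sample", "node", "count"])
    )
    unassigned = (
        assignments[assignments["node"] == -1].groupby("sample").size().to_dict()
    )
    for sample in assignments["sample"].unique():
        unassigned.setdefault(sample, 0)
    return TaxonProfile(
        counts=counts, metadata=metadata or {}, unassigned=unassigned
    )
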