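"""Structural model of the U4 snRNA and its paralog mapping to U4atac.

The U4 snRNA (gene *RNU4-2*) folds into a series of stems and loops that
mediate its interactions with U6 and with spliceosomal proteins.  This module
encodes the named structural regions in transcript (HGVS ``n.``) coordinates,
the kink-turn (k-turn) motif inside the 5' stem loop, base-pairing partners
within the 5' stem loop duplex, and a block alignment onto the minor
spliceosome paralog *RNU4ATAC*, whose structurally equivalent positions carry
well-classified pathogenic variants.

Coordinates throughout are 1-based with inclusive ends, matching HGVS ``n.``
nomenclature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml


class CoordinateError(ValueError):
    """A position falls outside the gene's transcript coordinates."""


@dataclass(frozen=True)
class RegionSpan:
    """A named structural region, 1-based inclusive span.

    ``pm1_eligible`` marks regions treated as mutational hotspots for the
    ACMG PM1 criterion (Stem II and the Sm protein binding site at the region
    level; k-turn positions are flagged separately on the gene model).
    """

    name: str
    start: int
    end: int
    pm1_eligible: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region {self.name}: start {self.start} > end {self.end}")

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class ParalogAlignment:
    """Block alignment between two structurally homologous snRNA genes.

    Each block ``(src_start, src_end, dst_start, dst_end)`` maps a run of
    source positions onto target positions at a constant offset.  Sequences
    are optional; when present they enable reference-base identity checks.
    """

    source_gene: str
    target_gene: str
    blocks: tuple[tuple[int, int, int, int], ...]
    source_sequence: Optional[str] = None
    target_sequence: Optional[str] = None

    def __post_init__(self) -> None:
        for b in self.blocks:
            s0, s1, d0, d1 = b
            if s1 - s0 != d1 - d0:
                raise ValueError(f"alignment block {b} has unequal lengths")
        # non-overlap on both genes
        for axis, (lo, hi) in (("source", (0, 1)), ("target", (2, 3))):
            spans = sorted((b[lo], b[hi]) for b in self.blocks)
            for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
                if b0 <= a1:
                    raise ValueError(f"alignment blocks overlap on {axis} gene")


@dataclass
class SnrnaGeneModel:
    """Gene sequence plus named structural annotation for one snRNA gene."""

    gene_id: str
    length: int
    regions: list[RegionSpan]
    kturn_spans: list[tuple[int, int]] = field(default_factory=list)
    pairing_map: dict[int, int] = field(default_factory=dict)
    renu_critical_regions: frozenset[str] = frozenset()
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sequence is not None:
            self.sequence = self.sequence.upper().replace("U", "T")
            if len(self.sequence) != self.length:
                raise ValueError(
                    f"sequence length {len(self.sequence)} != declared length {self.length}"
                )
        for r in self.regions:
            if r.start < 1 or r.end > self.length:
                raise CoordinateError(f"region {r.name} outside [1, {self.length}]")
        spans = sorted((r.start, r.end) for r in self.regions)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 <= a1:
                raise ValueError("primary regions overlap")
        loop = self._stem_loop_5p()
        for s, e in self.kturn_spans:
            if loop is None or s < loop.start or e > loop.end:
                raise ValueError(f"k-turn span ({s}, {e}) outside the 5' stem loop")
        for p, q in self.pairing_map.items():
            if p == q:
                raise ValueError(f"self-pairing at position {p}")
            if self.pairing_map.get(q) != p:
                raise ValueError(f"pairing map is not an involution at {p}<->{q}")
            if loop is not None and not (p in loop and q in loop):
                raise ValueError(f"pairing {p}<->{q} outside the 5' stem loop")

    def _stem_loop_5p(self) -> Optional[RegionSpan]:
        for r in self.regions:
            if r.name.startswith("5'"):
                return r
        return None

    def ref_base(self, pos: int) -> Optional[str]:
        if self.sequence is None:
            return None
        self._check_pos(pos)
        return self.sequence[pos - 1]

    def _check_pos(self, pos: int) -> None:
        if not 1 <= pos <= self.length:
            raise CoordinateError(
                f"position {pos} outside [1, {self.length}] for {self.gene_id}"
            )

    # -- construction -----------------------------------------------------

    @classmethod
    def from_config(cls, cfg: Mapping, sequence: Optional[str] = None) -> "SnrnaGeneModel":
        regions = [
            RegionSpan(
                name=r["name"],
                start=int(r["start"]),
                end=int(r["end"]),
                pm1_eligible=bool(r.get("pm1_eligible", False)),
            )
            for r in cfg["regions"]
        ]
        pairing: dict[int, int] = {}
        for p, q in cfg.get("pairing_pairs", []):
            pairing[int(p)] = int(q)
            pairing[int(q)] = int(p)
        length = int(cfg["length"]) if sequence is None else len(sequence)
        return cls(
            gene_id=cfg["gene_id"],
            length=length,
            regions=regions,
            kturn_spans=[(int(s), int(e)) for s, e in cfg.get("kturn_spans", [])],
            pairing_map=pairing,
            renu_critical_regions=frozenset(cfg.get("renu_critical_regions", [])),
            sequence=sequence,
        )


def load_default_config() -> dict:
    """Packaged RNU4-2 structural configuration (region spans, k-turn, pairing,
    paralog alignment blocks, analysis thresholds)."""
    text = resources.files("rnu4kit.data").joinpath("rnu4_2_model.yaml").read_text()
    return yaml.safe_load(text)


def default_model(sequence: Optional[str] = None) -> SnrnaGeneModel:
    return SnrnaGeneModel.from_config(load_default_config(), sequence=sequence)


def default_alignment(
    source_sequence: Optional[str] = None, target_sequence: Optional[str] = None
) -> ParalogAlignment:
    cfg = load_default_config()["paralog_alignment"]
    return ParalogAlignment(
        source_gene=cfg["source_gene"],
        target_gene=cfg["target_gene"],
        blocks=tuple(tuple(int(x) for x in b) for b in cfg["blocks"]),
        source_sequence=source_sequence,
        target_sequence=target_sequence,
    )


# -- operations -----------------------------------------------------------


UNASSIGNED = "unassigned"


def annotate_region(pos: int, model: SnrnaGeneModel) -> tuple[str, bool]:
    """Primary region label for a position plus a k-turn flag.

    Positions falling between the named spans are labeled ``"unassigned"``.
    The k-turn flag is True iff the position lies in one of the k-turn spans
    (which sit inside the 5' stem loop).
    """
    model._check_pos(pos)
    label = UNASSIGNED
    for r in model.regions:
        if pos in r:
            label = r.name
            break
    in_kturn = any(s <= pos <= e for s, e in model.kturn_spans)
    return label, in_kturn


def is_pm1_eligible(pos: int, model: SnrnaGeneModel) -> bool:
    """PM1 hotspot membership: Stem II, the k-turn, or the Sm protein site."""
    label, in_kturn = annotate_region(pos, model)
    if in_kturn:
        return True
    return any(r.name == label and r.pm1_eligible for r in model.regions)


def map_equivalent_position(pos: int, aln: ParalogAlignment) -> Optional[int]:
    """Map a source-gene position to the structurally equivalent target
    position, or None when the position is not covered by any block."""
    for s0, s1, d0, d1 in aln.blocks:
        if s0 <= pos <= s1:
            return d0 + (pos - s0)
    return None


@dataclass(frozen=True)
class EquivalenceRecord:
    """Outcome of looking up a variant's structural equivalent in the paralog."""

    position: int
    aligned_position: Optional[int]
    bases_identical: Optional[bool]  # None when either sequence is unavailable
    equivalent: bool                 # mappable and reference bases identical
    exact_match_classification: Optional[str]  # paralog-table class on exact match


PARALOG_TABLE_COLUMNS = ("gene", "hgvs_n", "classification")


def find_equivalent_variant(
    variant,
    aln: ParalogAlignment,
    paralog_table: Optional[pd.DataFrame] = None,
    require_same_alt: bool = True,
) -> EquivalenceRecord:
    """Look up the paralog equivalence status of a single-position substitution.

    Equivalence requires (a) the position maps through an alignment block and
    (b) the reference bases of the two genes are identical at the aligned
    positions.  An *exact match* additionally requires a paralog-table entry
    for the same substitution (same alternate base when ``require_same_alt``)
    classified in the table; its classification string is returned.
    """
    if paralog_table is not None:
        missing = [c for c in PARALOG_TABLE_COLUMNS if c not in paralog_table.columns]
        if missing:
            raise ValueError(f"paralog table missing columns: {missing}")
    pos = variant.start
    mapped = map_equivalent_position(pos, aln)
    if mapped is None:
        return EquivalenceRecord(pos, None, None, False, None)
    identical: Optional[bool] = None
    if aln.source_sequence is not None and aln.target_sequence is not None:
        src = aln.source_sequence[pos - 1].upper().replace("U", "T")
        dst = aln.target_sequence[mapped - 1].upper().replace("U", "T")
        identical = src == dst
    equivalent = bool(identical)
    classification = None
    if equivalent and paralog_table is not None and variant.vtype == "SNV":
        sub = paralog_table[paralog_table["gene"] == aln.target_gene]
        for _, row in sub.iterrows():
            from .variants import parse_hgvs_loose

            try:
                pv = parse_hgvs_loose(str(row["hgvs_n"]))
            except ValueError:
                continue
            if pv.vtype != "SNV" or pv.start != mapped:
                continue
            if require_same_alt and pv.alt_bases != variant.alt_bases:
                continue
            classification = str(row["classification"])
            break
    return EquivalenceRecord(pos, mapped, identical, equivalent, classification)


def pairing_partner(pos: int, model: SnrnaGeneModel) -> Optional[int]:
    """Base-pairing partner within the 5' stem loop duplex, or None."""
    return model.pairing_map.get(pos)


def affected_positions(variant) -> list[int]:
    """Reference positions touched by a variant.  Insertions affect both
    flanking positions; all other types affect their start..end span."""
    return list(range(variant.start, variant.end + 1))


def region_distribution(variants: Iterable, model: SnrnaGeneModel) -> pd.DataFrame:
    """Counts and percentages of variants per structural region.

    Each variant is counted once, under the region of its most 5' affected
    position.  K-turn positions are reported under their enclosing primary
    region (the 5' stem loop), with a separate ``n_kturn`` tally.
    """
    rows = []
    for v in variants:
        pos = min(affected_positions(v))
        label, in_kturn = annotate_region(pos, model)
        rows.append((label, in_kturn))
    if not rows:
        return pd.DataFrame(columns=["region", "n", "n_kturn", "percent"])
    df = pd.DataFrame(rows, columns=["region", "kturn"])
    out = (
        df.groupby("region", sort=False)
        .agg(n=("region", "size"), n_kturn=("kturn", "sum"))
        .reset_index()
    )
    out["percent"] = 100.0 * out["n"] / out["n"].sum()
    return out.sort_values("n", ascending=False, ignore_index=True)
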