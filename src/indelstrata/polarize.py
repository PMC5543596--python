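"""Calling 1-5 bp human-lineage indels from an 8-species multiple alignment.

The human reference is compared against seven primate outgroups
(chimpanzee, bonobo, gorilla, orangutan, gibbon, rhesus macaque,
marmoset by default).  A derived human indel is called only when all
seven outgroups carry an identical ancestral allele over the event
columns: this "homoplasy guard" protects against independent identical
events on an outgroup lineage flipping the inferred polarity.  Sites
where the outgroups disagree, mix gap and base states, or contain
ambiguous bases are routed to a rejection log rather than being called.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import AlignIO

__all__ = [
    "SpeciesConfig",
    "AlignmentBlock",
    "PolarizedIndel",
    "Rejection",
    "read_maf",
    "normalize_gaps",
    "call_reference_indels",
    "scan_alignment",
]

GAP = "-"
_VALID_BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DEFAULT_HUMAN = "hg19"
DEFAULT_OUTGROUPS = (
    "panTro4",
    "panpan1.1",
    "gorGor3",
    "ponAbe2",
    "nomLeu1",
    "rheMac3",
    "calJac3",
)


class MafParseError(ValueError):
    """Malformed MAF input (unequal row lengths, bad records...)."""


class SpeciesConfigError(ValueError):
    """A species label in the alignment is not declared in the config."""


@dataclass(frozen=True)
class SpeciesConfig:
    """Names the human (reference) assembly and the seven outgroups.

    MAF ``s`` lines carry ``assembly.chrom`` sources; the part before the
    first dot is matched against these labels.
    """

    human: str = DEFAULT_HUMAN
    outgroups: tuple[str, ...] = DEFAULT_OUTGROUPS

    def __post_init__(self) -> None:
        if len(self.outgroups) != 7:
            raise SpeciesConfigError(
                f"expected 7 outgroup labels, got {len(self.outgroups)}"
            )
        if self.human in self.outgroups:
            raise SpeciesConfigError("human label duplicated among outgroups")

    @property
    def all_species(self) -> tuple[str, ...]:
        return (self.human,) + self.outgroups


@dataclass
class AlignmentBlock:
    """One MAF block with all eight species, anchored on the human row.

    ``ref_start`` is 0-based on the human reference; after ingestion the
    block is always on the '+' strand of the human reference.  All gapped
    sequences have identical length.
    """

    ref_chrom: str
    ref_start: int
    seqs: dict[str, str]
    species_order: list[str]
    strand: str = "+"
    ref_src_size: int | None = None

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.seqs.values()}
        if len(lengths) > 1:
            raise MafParseError(
                f"unequal gapped row lengths {sorted(lengths)} in block at "
                f"{self.ref_chrom}:{self.ref_start}"
            )

    @property
    def ncols(self) -> int:
        return len(next(iter(self.seqs.values())))

    def human_seq(self, cfg: SpeciesConfig) -> str:
        return self.seqs[cfg.human]

    def ungapped_ref_length(self, cfg: SpeciesConfig) -> int:
        return sum(c != GAP for c in self.seqs[cfg.human])


@dataclass
class PolarizedIndel:
    """A single polarized 1-5 bp event on the human lineage.

    ``pos`` is the 1-based human-reference coordinate of the base
    immediately left of the event (the VCF anchor convention).  Alleles
    are stored unanchored: a deletion carries the deleted bases as its
    ancestral allele and an empty derived allele; an insertion the
    reverse.
    """

    chrom: str
    pos: int
    length: int
    event: str  # "insertion" | "deletion"
    ancestral_allele: str
    derived_allele: str
    origin: str  # "reference_scan" | "cohort_vcf"
    fixation: str | None = None  # "fixed" | "polymorphic"
    sharing: str | None = None  # "modern_specific" | "archaic_shared" | "uncovered"
    introgressed: bool = False
    pop_daf: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        diff = len(self.derived_allele) - len(self.ancestral_allele)
        if self.event == "insertion" and diff != self.length:
            raise ValueError("insertion requires derived longer by `length`")
        if self.event == "deletion" and diff != -self.length:
            raise ValueError("deletion requires derived shorter by `length`")

    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ancestral_allele, self.derived_allele)


@dataclass(frozen=True)
class Rejection:
    chrom: str
    pos: int  # best-effort anchor position, 1-based
    reason: str
    detail: str = ""


def _species_of(src: str, known: Iterable[str] = ()) -> str:
    """Assembly label of a MAF source string.

    Labels may themselves contain dots (panpan1.1), so configured labels
    are matched as longest ``label.`` prefixes before falling back to
    splitting at the first dot.
    """
    for label in sorted(known, key=len, reverse=True):
        if src == label or src.startswith(label + "."):
            return label
    return src.split(".", 1)[0]


def _revcomp_gapped(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_maf(path: str, cfg: SpeciesConfig | None = None) -> Iterator[AlignmentBlock]:
    """Stream alignment blocks from a MAF file.

    Blocks missing any of the eight configured species are dropped;
    blocks whose human row is on the '-' strand are reverse-complemented
    so every yielded block is '+'-anchored.  Species labels not declared
    in the config raise :class:`SpeciesConfigError`.
    """
    cfg = cfg or SpeciesConfig()
    known = set(cfg.all_species)
    try:
        alignments = AlignIO.parse(path, "maf")
        for aln in alignments:
            seqs: dict[str, str] = {}
            ann: dict[str, dict] = {}
            for rec in aln:
                sp = _species_of(rec.id, known)
                if sp not in known:
                    raise SpeciesConfigError(
                        f"species label {sp!r} (source {rec.id!r}) not in config"
                    )
                chrom = rec.id[len(sp) + 1 :] if rec.id.startswith(sp + ".") else rec.id
                seqs[sp] = str(rec.seq)
                ann[sp] = {
                    "chrom": chrom,
                    "start": rec.annotations["start"],
                    "size": rec.annotations["size"],
                    "strand": rec.annotations["strand"],
                    "srcSize": rec.annotations["srcSize"],
                }
            if set(seqs) != known:
                continue
            h = ann[cfg.human]
            block = AlignmentBlock(
                ref_chrom=h["chrom"],
                ref_start=h["start"],
                seqs=seqs,
                species_order=list(cfg.all_species),
                strand="+",
                ref_src_size=h["srcSize"],
            )
            if h["strand"] in (-1, "-"):
                block = _to_plus_strand(block, cfg, h)
            yield block
    except ValueError as exc:  # biopython raises ValueError on malformed MAF
        if isinstance(exc, (SpeciesConfigError, MafParseError)):
            raise
        raise MafParseError(f"malformed MAF file {path!r}: {exc}") from exc


def _to_plus_strand(block: AlignmentBlock, cfg: SpeciesConfig, human_ann: dict) -> AlignmentBlock:
    """Reverse-complement a '-'-anchored block onto the '+' human strand."""
    size = human_ann["size"]
    src_size = human_ann["srcSize"]
    new_start = src_size - (human_ann["start"] + size)
    return AlignmentBlock(
        ref_chrom=block.ref_chrom,
        ref_start=new_start,
        seqs={sp: _revcomp_gapped(s) for sp, s in block.seqs.items()},
        species_order=block.species_order,
        strand="+",
        ref_src_size=src_size,
    )


# ---------------------------------------------------------------------------
# gap normalization


def _gap_runs(seq: str) -> list[tuple[int, int]]:
    """Maximal gap runs as half-open column intervals."""
    runs = []
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] == GAP:
            j = i
            while j < n and seq[j] == GAP:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def _shift_runs_left(seq: str, counterpart: str) -> str:
    """Left-shift each gap run of ``seq`` while the move is equivalent.

    A run at columns [i, j) may shift one column left when the character
    at i-1 equals the counterpart row's base at column j-1 (the repeat
    context of VCF left-alignment); the shifted alignment pairs the
    moved base with an identical base, so no information changes.
    """
    chars = list(seq)
    for i, j in _gap_runs(seq):
        while (
            i > 0
            and chars[i - 1] != GAP
            and counterpart[j - 1] != GAP
            and chars[i - 1].upper() == counterpart[j - 1].upper()
        ):
            chars[j - 1] = chars[i - 1]
            chars[i - 1] = GAP
            i -= 1
            j -= 1
    return "".join(chars)


def normalize_gaps(block: AlignmentBlock, cfg: SpeciesConfig | None = None) -> AlignmentBlock:
    """Canonicalize gap placement (leftmost within repeats), drop all-gap columns.

    Each row's gap runs are shifted left as far as the repeat context
    allows, using the human row as the counterpart for outgroup gaps and
    the first ungapped outgroup for human gaps.  The operation is
    idempotent and never changes any row's ungapped sequence.
    """
    cfg = cfg or SpeciesConfig()
    new_seqs = dict(block.seqs)
    # shifting one row can open further shifts in rows that use it as
    # counterpart, so iterate to a fixpoint (bounded by the column count)
    for _ in range(block.ncols + 1):
        human = new_seqs[cfg.human]
        # counterpart for human gaps: an outgroup row (they must agree for a
        # call anyway; use the first outgroup)
        counterpart_for_human = new_seqs[cfg.outgroups[0]]
        step = {}
        for sp, seq in new_seqs.items():
            counterpart = counterpart_for_human if sp == cfg.human else human
            step[sp] = _shift_runs_left(seq, counterpart)
        ncols = len(step[cfg.human])
        keep = [c for c in range(ncols) if any(step[sp][c] != GAP for sp in step)]
        if len(keep) != ncols:
            step = {sp: "".join(s[c] for c in keep) for sp, s in step.items()}
        if step == new_seqs:
            break
        new_seqs = step
    return dataclasses.replace(block, seqs=new_seqs)


# ---------------------------------------------------------------------------
# calling


def _indel_runs(block: AlignmentBlock, cfg: SpeciesConfig) -> list[tuple[int, int]]:
    """Maximal runs of columns containing a gap in any species."""
    any_gap = [
        any(block.seqs[sp][c] == GAP for sp in cfg.all_species)
        for c in range(block.ncols)
    ]
    runs = []
    i = 0
    n = block.ncols
    while i < n:
        if any_gap[i]:
            j = i
            while j < n and any_gap[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def call_reference_indels(
    block: AlignmentBlock,
    cfg: SpeciesConfig | None = None,
    min_len: int = 1,
    max_len: int = 5,
) -> tuple[list[PolarizedIndel], list[Rejection]]:
    """Call human-lineage indels in one (normalized) block.

    A deletion is emitted for a human gap run whose columns carry one
    identical ungapped allele in all seven outgroups; an insertion for a
    human base run gapped in all seven outgroups.  Everything else in a
    gap-containing run is a rejection with a reason code:

    - ``outgroup_disagreement``: outgroups ungapped but not identical
    - ``mixed_gap_base``: gap/base states mixed across species (includes
      homoplasic events where an outgroup shares the human state)
    - ``ambiguous_base``: N or soft-masked base within event columns
    - ``too_long``: run longer than ``max_len``
    - ``complex_region``: another gap run within one column
    - ``block_edge``: no anchoring human base to the left
    """
    cfg = cfg or SpeciesConfig()
    human = block.seqs[cfg.human]
    out_rows = [block.seqs[sp] for sp in cfg.outgroups]
    # human reference position (0-based count of human bases strictly left
    # of each column); pos of base left of run starting at column i is
    # ref_start + nbases[i] (1-based anchor).
    nbases = [0] * (block.ncols + 1)
    for c in range(block.ncols):
        nbases[c + 1] = nbases[c] + (human[c] != GAP)

    runs = _indel_runs(block, cfg)
    calls: list[PolarizedIndel] = []
    rejects: list[Rejection] = []

    def anchor_pos(i: int) -> int:
        return block.ref_start + nbases[i]

    for idx, (i, j) in enumerate(runs):
        pos = anchor_pos(i)
        cols = range(i, j)
        human_gapped = [human[c] == GAP for c in cols]
        out_gap_counts = [sum(row[c] == GAP for row in out_rows) for c in cols]

        # adjacency to another run within one column
        near = (idx > 0 and i - runs[idx - 1][1] <= 1) or (
            idx + 1 < len(runs) and runs[idx + 1][0] - j <= 1
        )
        if near:
            rejects.append(Rejection(block.ref_chrom, pos, "complex_region"))
            continue

        if all(human_gapped) and all(g == 0 for g in out_gap_counts):
            # deletion candidate: outgroups must be identical, clean bases
            out_alleles = {"".join(row[c] for c in cols) for row in out_rows}
            if len(out_alleles) > 1:
                rejects.append(
                    Rejection(block.ref_chrom, pos, "outgroup_disagreement")
                )
                continue
            allele = out_alleles.pop()
            if not set(allele) <= _VALID_BASES:
                rejects.append(Rejection(block.ref_chrom, pos, "ambiguous_base"))
                continue
            length = j - i
            if length > max_len or length < min_len:
                rejects.append(Rejection(block.ref_chrom, pos, "too_long"))
                continue
            if nbases[i] == 0:
                rejects.append(Rejection(block.ref_chrom, pos, "block_edge"))
                continue
            calls.append(
                PolarizedIndel(
                    chrom=block.ref_chrom,
                    pos=pos,
                    length=length,
                    event="deletion",
                    ancestral_allele=allele,
                    derived_allele="",
                    origin="reference_scan",
                )
            )
        elif not any(human_gapped) and all(g == 7 for g in out_gap_counts):
            # insertion candidate: allele comes from the human row
            allele = "".join(human[c] for c in cols)
            if not set(allele) <= _VALID_BASES:
                rejects.append(Rejection(block.ref_chrom, pos, "ambiguous_base"))
                continue
            length = j - i
            if length > max_len or length < min_len:
                rejects.append(Rejection(block.ref_chrom, pos, "too_long"))
                continue
            if nbases[i] == 0:
                rejects.append(Rejection(block.ref_chrom, pos, "block_edge"))
                continue
            calls.append(
                PolarizedIndel(
                    chrom=block.ref_chrom,
                    pos=pos,
                    length=length,
                    event="insertion",
                    ancestral_allele="",
                    derived_allele=allele,
                    origin="reference_scan",
                )
            )
        else:
            rejects.append(Rejection(block.ref_chrom, pos, "mixed_gap_base"))
    return calls, rejects


CALL_COLUMNS = ["chrom", "pos", "length", "event", "ancestral", "derived", "origin"]
REJECT_COLUMNS = ["chrom", "pos", "reason", "detail"]


def calls_to_frame(calls: Sequence[PolarizedIndel]) -> pd.DataFrame:
    rows = [
        (c.chrom, c.pos, c.length, c.event, c.ancestral_allele, c.derived_allele, c.origin)
        for c in calls
    ]
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def scan_alignment(
    blocks: Iterable[AlignmentBlock],
    cfg: SpeciesConfig | None = None,
    min_len: int = 1,
    max_len: int = 5,
    normalize: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate per-block calls into one sorted, de-duplicated table.

    Duplicate calls from overlapping blocks collapse to one record;
    contradictory calls (same chrom/pos, different alleles) are both
    dropped and logged with reason ``contradictory_overlap``.
    Returns ``(calls, rejections)`` DataFrames.
    """
    cfg = cfg or SpeciesConfig()
    all_calls: list[PolarizedIndel] = []
    all_rejects: list[Rejection] = []
    for block in blocks:
        if normalize:
            block = normalize_gaps(block, cfg)
        calls, rejects = call_reference_indels(block, cfg, min_len, max_len)
        all_calls.extend(calls)
        all_rejects.extend(rejects)

    calls_df = calls_to_frame(all_calls)
    rej_rows = [(r.chrom, r.pos, r.reason, r.detail) for r in all_rejects]
    if not calls_df.empty:
        calls_df = calls_df.drop_duplicates(
            subset=["chrom", "pos", "ancestral", "derived"]
        )
        # contradictory overlaps: same position, different alleles
        dup = calls_df.duplicated(subset=["chrom", "pos"], keep=False)
        for _, row in calls_df[dup].iterrows():
            rej_rows.append((row.chrom, row.pos, "contradictory_overlap", ""))
        calls_df = calls_df[~dup]
        calls_df = calls_df.sort_values(["chrom", "pos"]).reset_index(drop=True)
    rejects_df = pd.DataFrame(rej_rows, columns=REJECT_COLUMNS)
    return calls_df, rejects_df
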