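"""Regulatory region construction: fixed promoters and chromatin refinement.

The default regulatory region of a gene is the proximal promoter, 1500 bp
upstream to 500 bp downstream of its transcription start site.  When a
chromatin-state segmentation (e.g. a 15-state histone-mark HMM) is available,
promoters are refined in two steps: positions overlapping "closed" states
(Polycomb-repressed, heterochromatin/low-signal) are masked out of scoring,
and a promoter end that falls inside an "open" state is extended to the full
extent of that open segment.  All coordinates are 0-based half-open (BED).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from affinityscan.affinity import SequenceRecord

#: default partition of the 15-state chromatin HMM vocabulary: the two states
#: treated as closed chromatin; everything else is open.
DEFAULT_CLOSED_STATES = frozenset({"Polycomb repressed", "Heterochrom; low signal"})

PROMOTER_UP = 1500
PROMOTER_DOWN = 500


@dataclass(frozen=True)
class TssRecord:
    gene_id: str
    chrom: str
    tss: int  # 0-based position of the first transcribed base
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"{self.gene_id}: TSS position must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class ChromatinSegment:
    chrom: str
    start: int
    end: int
    state: str
    openness: str  # "open" or "closed"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"segment {self.chrom}:{self.start}-{self.end}: start must be < end")
        if self.openness not in ("open", "closed"):
            raise ValueError(f"openness must be 'open' or 'closed', got {self.openness!r}")


@dataclass(frozen=True)
class Region:
    """A gene's regulatory region: ordered disjoint intervals on one chromosome.

    ``fully_closed`` marks regions whose promoter fell entirely into closed
    chromatin; such regions carry no intervals and are skipped by sequence
    extraction.
    """

    gene_id: str
    chrom: str
    intervals: tuple[tuple[int, int], ...]
    strand: str
    provenance: str = "fixed_promoter"
    fully_closed: bool = False

    def __post_init__(self) -> None:
        iv = tuple((int(a), int(b)) for a, b in self.intervals)
        if not iv and not self.fully_closed:
            raise ValueError(f"{self.gene_id}: empty region not flagged fully_closed")
        for a, b in iv:
            if a >= b or a < 0:
                raise ValueError(f"{self.gene_id}: bad interval [{a}, {b})")
        for (_, b1), (a2, _) in zip(iv, iv[1:]):
            if a2 < b1:
                raise ValueError(f"{self.gene_id}: intervals overlap or are unsorted")
        object.__setattr__(self, "intervals", iv)

    @property
    def span(self) -> tuple[int, int]:
        return self.intervals[0][0], self.intervals[-1][1]

    @property
    def total_length(self) -> int:
        return sum(b - a for a, b in self.intervals)


def promoter_from_tss(tss: TssRecord, up: int = PROMOTER_UP, down: int = PROMOTER_DOWN) -> Region:
    """Fixed promoter window around a TSS, oriented by strand, clipped at 0.

    On the plus strand the region is [tss - up, tss + down); on the minus
    strand upstream lies at higher coordinates, giving [tss - down, tss + up).
    """
    if tss.strand == "+":
        start, end = tss.tss - up, tss.tss + down
    else:
        start, end = tss.tss - down, tss.tss + up
    start = max(start, 0)
    return Region(
        gene_id=tss.gene_id,
        chrom=tss.chrom,
        intervals=((start, end),),
        strand=tss.strand,
        provenance="fixed_promoter",
    )


def _overlapping_open(segments: list[ChromatinSegment], chrom: str, start: int, end: int):
    return [
        s
        for s in sorted(segments, key=lambda s: s.start)
        if s.chrom == chrom and s.openness == "open" and s.start < end and s.end > start
    ]


def refine_with_chromatin(region: Region, segments: list[ChromatinSegment]) -> Region:
    """Mask closed-chromatin positions and extend ends through open segments.

    Positions of the region overlapping closed states are removed.  If an end
    of the region lies inside an open segment, the region is extended to that
    segment's boundary, capturing the full open stretch the promoter touches.
    Idempotent: a refined region's ends already sit on open-segment
    boundaries, so refining again changes nothing.
    """
    chroms = {s.chrom for s in segments}
    if region.chrom not in chroms:
        raise ValueError(f"{region.gene_id}: chromosome {region.chrom!r} absent from segmentation")
    start, end = region.span
    open_segs = _overlapping_open(segments, region.chrom, start, end)
    if not open_segs:
        return Region(
            gene_id=region.gene_id,
            chrom=region.chrom,
            intervals=(),
            strand=region.strand,
            provenance="chromatin_refined",
            fully_closed=True,
        )
    # extend through the open segments containing the region's ends
    new_start = min(open_segs[0].start, start) if open_segs[0].start <= start < open_segs[0].end else start
    new_end = max(open_segs[-1].end, end) if open_segs[-1].start < end <= open_segs[-1].end else end
    kept = [
        (max(s.start, new_start), min(s.end, new_end))
        for s in _overlapping_open(segments, region.chrom, new_start, new_end)
    ]
    merged: list[tuple[int, int]] = []
    for a, b in kept:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return Region(
        gene_id=region.gene_id,
        chrom=region.chrom,
        intervals=tuple(merged),
        strand=region.strand,
        provenance="chromatin_refined",
    )


def extract_sequences(regions: list[Region], genome) -> list[SequenceRecord]:
    """Pull each region's sequence from a genome (mapping chrom -> sequence).

    ``genome`` may be a pyfaidx.Fasta, a plain dict of strings, or any mapping
    supporting ``genome[chrom][start:end]``.  Multi-interval regions are
    concatenated in genomic order with a masked junction base inserted between
    intervals, so no scoring window can span a genomic gap.  Fully-closed
    regions are skipped.  Sequences are reported on the plus strand (TBA is
    strand-symmetric, so orientation is immaterial downstream).
    """
    records: list[SequenceRecord] = []
    for region in regions:
        if region.fully_closed:
            continue
        chrom_seq = genome[region.chrom]
        chrom_len = len(chrom_seq)
        parts: list[str] = []
        mask: set[int] = set()
        offset = 0
        for k, (a, b) in enumerate(region.intervals):
            if b > chrom_len:
                raise ValueError(
                    f"region {region.gene_id!r}: interval [{a}, {b}) exceeds "
                    f"chromosome {region.chrom!r} length {chrom_len}"
                )
            if k > 0:
                parts.append("N")  # junction spacer: windows crossing it are skipped
                mask.add(offset)
                offset += 1
            piece = str(chrom_seq[a:b]).upper()
            parts.append(piece)
            offset += len(piece)
        records.append(SequenceRecord(id=region.gene_id, bases="".join(parts), mask=frozenset(mask)))
    return records


def read_tss_table(path: str | Path) -> list[TssRecord]:
    """Read a BED6-like TSV (chrom, start, end, gene_id, score, strand).

    The TSS is the start coordinate for + entries and end - 1 for - entries.
    """
    out: list[TssRecord] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise ValueError(f"{path}:{lineno}: expected >= 6 BED fields, got {len(fields)}")
        chrom, start, end, gene_id, _score, strand = fields[:6]
        tss = int(start) if strand == "+" else int(end) - 1
        out.append(TssRecord(gene_id=gene_id, chrom=chrom, tss=tss, strand=strand))
    return out


def read_state_map(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV mapping state label -> open|closed."""
    mapping: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        label, openness = line.rstrip("\n").split("\t")
        if openness not in ("open", "closed"):
            raise ValueError(f"{path}: openness must be open|closed, got {openness!r}")
        mapping[label] = openness
    return mapping


def read_segmentation(path: str | Path, state_map: dict[str, str] | None = None) -> list[ChromatinSegment]:
    """Read a BED4 segmentation (chrom, start, end, state_label).

    Without an explicit state map, states named in DEFAULT_CLOSED_STATES are
    closed and all others open.
    """
    segments: list[ChromatinSegment] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 4:
            raise ValueError(f"{path}:{lineno}: expected >= 4 BED fields, got {len(fields)}")
        chrom, start, end, state = fields[:4]
        if state_map is not None:
            openness = state_map.get(state)
            if openness is None:
                raise ValueError(f"{path}:{lineno}: state {state!r} absent from state map")
        else:
            openness = "closed" if state in DEFAULT_CLOSED_STATES else "open"
        segments.append(ChromatinSegment(chrom=chrom, start=int(start), end=int(end), state=state, openness=openness))
    return segments
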