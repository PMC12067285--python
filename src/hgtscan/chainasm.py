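"""Assembly of the transferred element's block structure from junctions.

The copy-number step segments are the blocks; structural-variant junctions
pair up their ends.  Starting from a seed terminus (a segment end with no
partner junction) the walk alternates segment traversal and junction hops
until it reaches the opposite terminus, emitting every visited segment as an
oriented block.  A block is '+' when entered through its left (lower
coordinate) end and '-' when entered through its right end.

Breakends carry 1-based positions and a side ('left' attaches at a segment
start, 'right' at a segment end); in BEDPE the strand column encodes the
side ('+' = right, '-' = left).  Breakend-to-segment-end matching uses a
configurable tolerance because copy-number breakpoints are only
window-resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ChainBranchingError, ConfigError

DEFAULT_TOLERANCE = 5_000
DEFAULT_MIN_SUPPORT = 3
DEFAULT_CENTROMERE_TOL = 500_000  # acrocentric assumption: centromere at position 0


@dataclass(frozen=True)
class Breakend:
    chrom: str
    pos: int  # 1-based
    side: str  # 'left' | 'right'


@dataclass(frozen=True)
class Junction:
    a: Breakend
    b: Breakend
    support: int = DEFAULT_MIN_SUPPORT


@dataclass(frozen=True)
class Block:
    chrom: str
    start: int  # 0-based half-open
    end: int
    orientation: str  # '+' | '-'
    order: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ChainElement:
    blocks: list[Block]
    circular: bool = False
    termini: tuple[str, str] = ("internal", "internal")
    terminus_breakends: tuple[Breakend, Breakend] | None = None

    @property
    def total_length(self) -> int:
        return sum(b.length for b in self.blocks)


@dataclass(frozen=True)
class ChainSummary:
    n_blocks: int
    n_chromosomes: int
    total_length: int
    termini: tuple[str, str]


def junctions_from_bedpe(df: pd.DataFrame, min_support: int = DEFAULT_MIN_SUPPORT) -> list[Junction]:
    """Junction objects from a BEDPE table (strand '+' = right side)."""
    out = []
    for _, r in df.iterrows():
        support = int(r.get("support", DEFAULT_MIN_SUPPORT))
        if support < min_support:
            continue
        out.append(
            Junction(
                Breakend(r["chrom1"], int(r["end1"]), "right" if r["strand1"] == "+" else "left"),
                Breakend(r["chrom2"], int(r["end2"]), "right" if r["strand2"] == "+" else "left"),
                support,
            )
        )
    return out


def _segment_ends(segments: pd.DataFrame):
    """(segment index, end side) -> 1-based breakend position."""
    ends = {}
    for i, r in segments.reset_index(drop=True).iterrows():
        ends[(i, "left")] = Breakend(r["chrom"], int(r["start"]) + 1, "left")
        ends[(i, "right")] = Breakend(r["chrom"], int(r["end"]), "right")
    return ends

def _match(breakend: Breakend, ends: dict, tol: int):
    """Segment end within tolerance of a junction breakend, or None."""
    hits = [
        key
        for key, be in ends.items()
        if be.chrom == breakend.chrom
        and be.side == breakend.side
        and abs(be.pos - breakend.pos) <= tol
    ]
    if len(hits) > 1:
        raise ConfigError(
            f"breakend {breakend} matches multiple segment ends at tolerance {tol}"
        )
    return hits[0] if hits else None


def assemble_chain(
    junctions: list[Junction] | pd.DataFrame,
    step_segments: pd.DataFrame,
    seed_terminus: Breakend | tuple[str, int, str] | None = None,
    tolerance: int = DEFAULT_TOLERANCE,
    min_support: int = DEFAULT_MIN_SUPPORT,
    chrom_lengths: dict[str, int] | None = None,
    centromere_tol: int = DEFAULT_CENTROMERE_TOL,
) -> ChainElement:
    """Walk junctions between step segments into an ordered, oriented chain.

    ``seed_terminus`` names the segment end where the walk starts; if None,
    a terminus (an end with no partner junction) is chosen deterministically
    (smallest chrom/pos).  A breakend joined to two or more partners raises
    :class:`ChainBranchingError`; returning to the seed marks the element
    circular rather than erroring.
    """
    if isinstance(junctions, pd.DataFrame):
        junctions = junctions_from_bedpe(junctions, min_support)
    junctions = [j for j in junctions if j.support >= min_support]
    segments = step_segments.reset_index(drop=True)
    ends = _segment_ends(segments)

    partner: dict[tuple[int, str], tuple[int, str]] = {}
    ambiguous = set()
    for j in junctions:
        ka = _match(j.a, ends, tolerance)
        kb = _match(j.b, ends, tolerance)
        if ka is None or kb is None:
            continue  # junction does not involve the step segments
        for src, dst in ((ka, kb), (kb, ka)):
            if src in partner and partner[src] != dst:
                ambiguous.add(src)
            partner[src] = dst
    if ambiguous:
        names = ", ".join(
            f"{ends[k].chrom}:{ends[k].pos}({ends[k].side})" for k in sorted(ambiguous)
        )
        raise ChainBranchingError(f"breakends with multiple partners: {names}")

    if seed_terminus is None:
        free = [k for k in ends if k not in partner]
        if not free:
            # fully cyclic: start anywhere, deterministically
            start_key = min(ends, key=lambda k: (ends[k].chrom, ends[k].pos, k[1]))
        else:
            start_key = min(free, key=lambda k: (ends[k].chrom, ends[k].pos, k[1]))
    else:
        if not isinstance(seed_terminus, Breakend):
            seed_terminus = Breakend(*seed_terminus)
        start_key = _match(seed_terminus, ends, tolerance)
        if start_key is None:
            raise ConfigError(f"seed terminus {seed_terminus} matches no segment end")

    blocks: list[Block] = []
    visited = set()
    circular = False
    key = start_key
    while True:
        seg_i, entry_side = key
        if seg_i in visited:
            circular = True
            break
        visited.add(seg_i)
        r = segments.iloc[seg_i]
        orientation = "+" if entry_side == "left" else "-"
        blocks.append(
            Block(r["chrom"], int(r["start"]), int(r["end"]), orientation, len(blocks))
        )
        exit_key = (seg_i, "right" if entry_side == "left" else "left")
        if exit_key not in partner:
            break
        key = partner[exit_key]

    first = blocks[0]
    last = blocks[-1]
    be_first = Breakend(
        first.chrom,
        first.start + 1 if first.orientation == "+" else first.end,
        "left" if first.orientation == "+" else "right",
    )
    be_last = Breakend(
        last.chrom,
        last.end if last.orientation == "+" else last.start + 1,
        "right" if last.orientation == "+" else "left",
    )
    termini = (
        _terminus_label(be_first, chrom_lengths, centromere_tol),
        _terminus_label(be_last, chrom_lengths, centromere_tol),
    )
    return ChainElement(blocks, circular, termini, (be_first, be_last))


def _terminus_label(be: Breakend, chrom_lengths, centromere_tol) -> str:
    if be.pos <= centromere_tol:
        return "centromeric"
    if chrom_lengths is not None:
        length = chrom_lengths.get(be.chrom)
        if length is not None and be.pos >= length - centromere_tol:
            return "telomeric"
    return "internal"


def summarize_element(chain: ChainElement) -> ChainSummary:
    """Block/chromosome/length summary of an assembled element."""
    if not chain.blocks:
        raise ConfigError("cannot summarize an empty chain")
    return ChainSummary(
        n_blocks=len(chain.blocks),
        n_chromosomes=len({b.chrom for b in chain.blocks}),
        total_length=chain.total_length,
        termini=chain.termini,
    )


def chain_to_frame(chain: ChainElement) -> pd.DataFrame:
    """Ordered BED-with-orientation representation of a chain."""
    return pd.DataFrame(
        [(b.chrom, b.start, b.end, b.order, b.orientation) for b in chain.blocks],
        columns=["chrom", "start", "end", "order", "orientation"],
    )
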