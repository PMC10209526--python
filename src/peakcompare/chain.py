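"""UCSC chain files and coordinate liftover between genome builds.

A chain file describes a pairwise genome alignment as a list of chains,
each a header line::

    chain score tName tSize tStrand tStart tEnd qName qSize qStrand qStart qEnd id

followed by ungapped alignment blocks (``size dt dq`` triples, the last
line a bare ``size``). Here *t* (target, in UCSC's naming) is the source
build of the liftover and *q* (query) the destination build; ``tStrand``
is always ``+`` while ``qStrand`` may be ``-``, in which case q
coordinates count from the far end of the destination chromosome.

An interval is lifted through the highest-scoring chain that overlaps it,
block by block; the lifted interval spans the mapped bases on the
destination chromosome. Intervals mapping to less than a minimum fraction
of their width (liftOver's minMatch, default 0.95 here) are dropped.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .core import normalize_build


@dataclass(frozen=True)
class AlignmentBlock:
    """One ungapped block, in source (t) and destination (q) chain-local
    coordinates. ``q_start`` is still in the chain's declared q strand."""

    t_start: int
    q_start: int
    size: int

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("alignment block size must be positive")


@dataclass(frozen=True)
class Chain:
    score: float
    t_name: str
    t_size: int
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    blocks: tuple[AlignmentBlock, ...] = field(default=())

    def __post_init__(self) -> None:
        for blk in self.blocks:
            if not (self.t_start <= blk.t_start
                    and blk.t_start + blk.size <= self.t_end):
                raise ValueError("alignment block outside declared chain span")

    def map_span(self, start: int, end: int) -> list[tuple[int, int]]:
        """Map source span [start, end) through this chain's blocks.

        Returns forward-strand destination spans, one per intersected block.
        """
        spans: list[tuple[int, int]] = []
        for blk in self.blocks:
            lo = max(start, blk.t_start)
            hi = min(end, blk.t_start + blk.size)
            if lo >= hi:
                continue
            q_lo = blk.q_start + (lo - blk.t_start)
            q_hi = q_lo + (hi - lo)
            if self.q_strand == "-":
                q_lo, q_hi = self.q_size - q_hi, self.q_size - q_lo
            spans.append((q_lo, q_hi))
        return spans


class ChainMap:
    """All chains of one source->target liftover, indexed by source chrom."""

    def __init__(self, chains: list[Chain],
                 source_build: Optional[str] = None,
                 target_build: Optional[str] = None) -> None:
        self.chains = list(chains)
        self.source_build = normalize_build(source_build)
        self.target_build = normalize_build(target_build)
        self._by_chrom: dict[str, list[Chain]] = {}
        for chain in self.chains:
            self._by_chrom.setdefault(chain.t_name, []).append(chain)
        for lst in self._by_chrom.values():
            lst.sort(key=lambda c: -c.score)

    def best_chain(self, chrom: str, start: int, end: int) -> Optional[Chain]:
        """Highest-scoring chain whose source span overlaps [start, end)."""
        for chain in self._by_chrom.get(chrom, ()):
            if chain.t_start < end and start < chain.t_end:
                return chain
        return None


_BUILD_PAIR_RE = re.compile(r"([A-Za-z]{2}\d+|GRCh\d+)To([A-Za-z]{2}\d+|GRCh\d+)")


def _infer_builds(path: Path) -> tuple[Optional[str], Optional[str]]:
    match = _BUILD_PAIR_RE.search(path.name)
    if not match:
        return None, None
    src, dst = match.group(1), match.group(2)
    return src[0].lower() + src[1:], dst[0].lower() + dst[1:]


def read_chain(path: os.PathLike | str,
               source_build: Optional[str] = None,
               target_build: Optional[str] = None) -> ChainMap:
    """Parse a UCSC chain file.

    Builds not passed explicitly are inferred from a ``<src>To<Dst>``
    pattern in the filename (e.g. ``hg19ToHg38.over.chain``) when present.
    """
    path = Path(path)
    if source_build is None or target_build is None:
        inferred_src, inferred_dst = _infer_builds(path)
        source_build = source_build or inferred_src
        target_build = target_build or inferred_dst
    chains: list[Chain] = []
    header: Optional[list[str]] = None
    blocks: list[AlignmentBlock] = []
    t_cursor = q_cursor = 0

    def finish() -> None:
        nonlocal header, blocks
        if header is None:
            return
        (_, score, t_name, t_size, _t_strand, t_start, t_end,
         q_name, q_size, q_strand, q_start, q_end) = header[:12]
        chains.append(Chain(
            score=float(score), t_name=t_name, t_size=int(t_size),
            t_start=int(t_start), t_end=int(t_end),
            q_name=q_name, q_size=int(q_size), q_strand=q_strand,
            q_start=int(q_start), q_end=int(q_end), blocks=tuple(blocks)))
        header, blocks = None, []

    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("chain"):
                finish()
                header = line.split()
                if len(header) < 12:
                    raise ValueError(f"chain header at line {lineno} is truncated")
                t_cursor, q_cursor = int(header[5]), int(header[10])
                continue
            if header is None:
                raise ValueError(f"alignment block before any chain header (line {lineno})")
            parts = [int(x) for x in line.split()]
            size = parts[0]
            blocks.append(AlignmentBlock(t_start=t_cursor, q_start=q_cursor, size=size))
            if len(parts) == 3:
                t_cursor += size + parts[1]
                q_cursor += size + parts[2]
            else:
                t_cursor += size
                q_cursor += size
    finish()
    return ChainMap(chains, source_build=source_build, target_build=target_build)


def write_chain(chainmap: ChainMap, path: os.PathLike | str) -> Path:
    """Serialise a ChainMap back to UCSC chain format."""
    path = Path(path)
    with open(path, "w") as handle:
        for idx, chain in enumerate(chainmap.chains, start=1):
            handle.write(
                f"chain {chain.score:g} {chain.t_name} {chain.t_size} + "
                f"{chain.t_start} {chain.t_end} {chain.q_name} {chain.q_size} "
                f"{chain.q_strand} {chain.q_start} {chain.q_end} {idx}\n")
            blocks = chain.blocks
            for i, blk in enumerate(blocks):
                if i + 1 < len(blocks):
                    nxt = blocks[i + 1]
                    dt = nxt.t_start - (blk.t_start + blk.size)
                    dq = nxt.q_start - (blk.q_start + blk.size)
                    handle.write(f"{blk.size} {dt} {dq}\n")
                else:
                    handle.write(f"{blk.size}\n")
            handle.write("\n")
    return path


def identity_chain(chrom_sizes: dict[str, int],
                   source_build: Optional[str] = None,
                   target_build: Optional[str] = None) -> ChainMap:
    """A chain mapping every chromosome onto itself unchanged."""
    chains = [
        Chain(score=1000.0, t_name=name, t_size=size, t_start=0, t_end=size,
              q_name=name, q_size=size, q_strand="+", q_start=0, q_end=size,
              blocks=(AlignmentBlock(0, 0, size),))
        for name, size in chrom_sizes.items()
    ]
    return ChainMap(chains, source_build=source_build, target_build=target_build)


def shift_chain(chrom_shifts: dict[str, int], chrom_sizes: dict[str, int],
                source_build: Optional[str] = None,
                target_build: Optional[str] = None,
                target_sizes: Optional[dict[str, int]] = None) -> ChainMap:
    """A chain shifting each chromosome by a constant offset.

    A positive shift of +k maps source position x to x+k. The aligned block
    covers the largest span valid on both sides.
    """
    chains = []
    for name, size in chrom_sizes.items():
        k = chrom_shifts.get(name, 0)
        q_size = (target_sizes or chrom_sizes)[name]
        t_lo = max(0, -k)
        t_hi = min(size, q_size - k)
        if t_hi <= t_lo:
            continue
        chains.append(Chain(
            score=1000.0, t_name=name, t_size=size, t_start=t_lo, t_end=t_hi,
            q_name=name, q_size=q_size, q_strand="+",
            q_start=t_lo + k, q_end=t_hi + k,
            blocks=(AlignmentBlock(t_lo, t_lo + k, t_hi - t_lo),)))
    return ChainMap(chains, source_build=source_build, target_build=target_build)
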