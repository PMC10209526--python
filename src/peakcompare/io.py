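"""Reading and writing BED-family peak formats.

Supported dialects:

* ``bed3`` / ``bed6`` — plain BED.
* ``narrowPeak`` (BED6+4) and ``broadPeak`` (BED6+3) — ENCODE formats with
  signalValue and -log10 p/q columns (plus summit offset for narrowPeak).
* ``seacr`` — SEACR's 6-column output, with the *total signal* in column 4
  (mapped onto ``signal_value``) and the max-signal region string in
  column 6 (kept as the interval name). Selected via ``format_hint`` only.
* ``homer`` — HOMER pos files: ``#``-prefixed headers, 1-based starts,
  columns PeakID/chr/start/end/strand/tag-count. Selected via
  ``format_hint`` only.

Auto-detection is by column count (10 -> narrowPeak, 9 -> broadPeak,
6 -> bed6, otherwise bed-N). MACS writes ``-1`` in the p/q columns when a
value was not computed; that placeholder is parsed as missing. Chromosome
names are taken verbatim — no "chr" prefix munging.
"""

from __future__ import annotations

import os
import warnings
from pathlib import Path
from typing import Optional

from .core import ChromSizes, GenomicInterval, PeakSet


def _parse_float(token: str, *, minus_one_missing: bool = False) -> Optional[float]:
    if token in (".", ""):
        return None
    value = float(token)
    if minus_one_missing and value == -1:
        return None
    return value


def _parse_name(token: str) -> Optional[str]:
    return None if token in (".", "") else token


def _label_from_path(path: os.PathLike | str) -> str:
    stem = Path(path).name
    for suffix in (".narrowPeak", ".broadPeak", ".bed", ".txt", ".pos"):
        if stem.endswith(suffix):
            return stem[: -len(suffix)]
    return stem


def _detect_format(n_columns: int) -> str:
    if n_columns >= 10:
        return "narrowPeak"
    if n_columns == 9:
        return "broadPeak"
    if n_columns >= 6:
        return "bed6"
    return "bed3"


def _parse_line(fields: list[str], fmt: str, lineno: int) -> GenomicInterval:
    try:
        chrom = fields[0]
        start, end = int(fields[1]), int(fields[2])
        kwargs: dict = {}
        if fmt == "seacr":
            # chrom start end total_signal max_signal max_signal_region
            if len(fields) > 3:
                kwargs["signal_value"] = _parse_float(fields[3])
            if len(fields) > 4:
                kwargs["score"] = _parse_float(fields[4])
            if len(fields) > 5:
                kwargs["name"] = _parse_name(fields[5])
        elif fmt in ("bed6", "narrowPeak", "broadPeak"):
            if len(fields) > 3:
                kwargs["name"] = _parse_name(fields[3])
            if len(fields) > 4:
                kwargs["score"] = _parse_float(fields[4])
            if len(fields) > 5 and fields[5] in ("+", "-", "."):
                kwargs["strand"] = fields[5]
            if fmt in ("narrowPeak", "broadPeak"):
                kwargs["signal_value"] = _parse_float(fields[6], minus_one_missing=True)
                kwargs["p_value"] = _parse_float(fields[7], minus_one_missing=True)
                kwargs["q_value"] = _parse_float(fields[8], minus_one_missing=True)
            if fmt == "narrowPeak":
                kwargs["summit_offset"] = int(fields[9])
        return GenomicInterval(chrom, start, end, **kwargs)
    except (ValueError, IndexError) as exc:
        raise ValueError(f"malformed record at line {lineno}: {exc}") from exc


def _parse_homer_line(fields: list[str], lineno: int) -> GenomicInterval:
    # PeakID chr start end strand [tag count ...]; starts are 1-based.
    try:
        name = _parse_name(fields[0])
        chrom = fields[1]
        start, end = int(fields[2]) - 1, int(fields[3])
        strand = fields[4] if len(fields) > 4 and fields[4] in ("+", "-", ".") else "."
        signal = _parse_float(fields[5]) if len(fields) > 5 else None
        return GenomicInterval(chrom, start, end, name=name, strand=strand,
                               signal_value=signal)
    except (ValueError, IndexError) as exc:
        raise ValueError(f"malformed HOMER record at line {lineno}: {exc}") from exc


def read_peaks(
    path: os.PathLike | str,
    format_hint: Optional[str] = None,
    label: Optional[str] = None,
    genome_build: Optional[str] = None,
) -> PeakSet:
    """Read a peak file into a sorted :class:`~peakcompare.core.PeakSet`.

    ``format_hint`` forces a dialect (required for ``seacr``/``homer``);
    without it the dialect is inferred from the column count of the first
    data line. Comment (``#``), ``track`` and ``browser`` lines are skipped.
    Malformed lines raise :class:`ValueError` naming the line number; an
    empty file yields an empty set with a warning.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    fmt = format_hint
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith(("track", "browser")):
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3 and fmt != "homer":
                raise ValueError(
                    f"malformed record at line {lineno}: fewer than 3 columns"
                )
            if fmt is None:
                fmt = _detect_format(len(fields))
            if fmt == "homer":
                intervals.append(_parse_homer_line(fields, lineno))
            else:
                intervals.append(_parse_line(fields, fmt, lineno))
    if not intervals:
        warnings.warn(f"{path} contains no peak records", stacklevel=2)
        fmt = fmt or "bed3"
    peaks = PeakSet(
        label=label if label is not None else _label_from_path(path),
        intervals=intervals,
        genome_build=genome_build,
        source_format=fmt,
    )
    peaks.strength_column = infer_strength_column(peaks)
    return peaks


def _fmt_num(value: Optional[float], missing: str = ".") -> str:
    if value is None:
        return missing
    if float(value).is_integer():
        return str(int(value))
    return repr(float(value))


def write_peaks(peaks: PeakSet, path: os.PathLike | str) -> Path:
    """Serialise a PeakSet as a tab-separated file in its ``source_format``.

    The writer inverts the reader exactly: ``read_peaks(write_peaks(x))``
    reproduces every parsed field (missing p/q values are emitted as the
    MACS ``-1`` placeholder for the ENCODE dialects).
    """
    path = Path(path)
    fmt = peaks.source_format
    lines = []
    for iv in peaks:
        if fmt == "bed3":
            fields = [iv.chrom, str(iv.start), str(iv.end)]
        elif fmt == "seacr":
            fields = [iv.chrom, str(iv.start), str(iv.end),
                      _fmt_num(iv.signal_value), _fmt_num(iv.score),
                      iv.name if iv.name is not None else "."]
        elif fmt == "homer":
            fields = [iv.name if iv.name is not None else ".",
                      iv.chrom, str(iv.start + 1), str(iv.end), iv.strand,
                      _fmt_num(iv.signal_value)]
        else:
            fields = [iv.chrom, str(iv.start), str(iv.end),
                      iv.name if iv.name is not None else ".",
                      _fmt_num(iv.score), iv.strand]
            if fmt in ("narrowPeak", "broadPeak"):
                fields += [_fmt_num(iv.signal_value, "-1"),
                           _fmt_num(iv.p_value, "-1"),
                           _fmt_num(iv.q_value, "-1")]
            if fmt == "narrowPeak":
                fields.append(str(iv.summit_offset if iv.summit_offset is not None else -1))
        lines.append("\t".join(fields))
    with open(path, "w") as handle:
        if fmt == "homer":
            handle.write("#PeakID\tchr\tstart\tend\tstrand\tNormalized Tag Count\n")
        for line in lines:
            handle.write(line + "\n")
    return path


def infer_strength_column(peaks: PeakSet) -> Optional[str]:
    """Pick the column used for peak-strength thresholding.

    Priority: ``q_value`` when present and varying, else ``signal_value``
    (which also carries the SEACR total signal and HOMER tag count), else
    ``score``. Returns None when no numeric column varies — a valid outcome
    (thresholding then degrades to keep-all).
    """
    for column in ("q_value", "signal_value", "score"):
        values = [getattr(iv, column) for iv in peaks]
        observed = [v for v in values if v is not None]
        if not observed:
            continue
        if len(set(observed)) > 1 or len(peaks) == 1:
            return column
    return None


def read_chrom_sizes(path: os.PathLike | str) -> ChromSizes:
    """Parse a UCSC chrom.sizes file (name <TAB> length)."""
    sizes = ChromSizes()
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"chrom.sizes line {lineno}: expected two columns")
            name = fields[0]
            if name in sizes:
                raise ValueError(f"chrom.sizes line {lineno}: duplicate chromosome {name!r}")
            try:
                sizes[name] = int(fields[1])
            except ValueError as exc:
                raise ValueError(f"chrom.sizes line {lineno}: {exc}") from exc
    return sizes
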