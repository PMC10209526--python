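"""One-call orchestration of the full comparison pipeline and the HTML
report.

:func:`run` takes a :class:`RunConfig`, standardizes every input peak
file, executes each enabled analysis in a fixed order and writes all
tables and figures under ``<outdir>/peakcompare_files``. A failure in an
optional analysis is logged with a reason and skipped — one broken
annotation never aborts the run. :func:`render_html` then assembles a
single self-contained HTML report with three sections: General Metrics,
Peak Overlap and Functional Annotation.
"""

from __future__ import annotations

import base64
import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from datetime import datetime
from html import escape
from pathlib import Path
from string import Template
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .annotation import (chromhmm_annotate, enrichment_test, feature_annotate,
                         peaks_to_genes, read_gene_bed, read_gmt,
                         read_segmentation, tss_profile)
from .binning import compute_corr, rebin_peaks
from .chain import read_chain
from .comparison import (overlap_matrix, precision_recall, stat_split,
                         upset_counts)
from .core import PeakSet, normalize_build
from .io import read_chrom_sizes, read_peaks
from .standardize import parse_picard_metrics, standardize_all
from . import plots

logger = logging.getLogger("peakcompare")

ALL_ANALYSES = ("upset", "stat", "precision_recall", "correlation",
                "chromhmm", "feature", "enrichment", "tss")


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    ``peaks`` maps sample labels to file paths; ``builds`` is a single
    build name or a role/label -> build mapping (roles: ``peakfiles``,
    ``reference``, ``blacklist``). Toggles default to on; analyses whose
    auxiliary inputs are missing are skipped with a logged reason.
    """

    peaks: dict[str, str]
    blacklist: str
    output_dir: str = "peakcompare_output"
    reference: Optional[str] = None
    builds: object = None
    target_build: Optional[str] = None
    chains: list[str] = field(default_factory=list)
    chrom_sizes: Optional[str] = None
    segmentation: Optional[str] = None
    genes: Optional[str] = None
    gmt: Optional[str] = None
    picard: dict[str, str] = field(default_factory=dict)
    analyses: dict[str, bool] = field(default_factory=dict)
    bin_width: int = 1000
    n_thresholds: int = 11
    corr_method: str = "spearman"
    tss_window: int = 3000
    tss_bin: int = 100
    promoter_upstream: int = 2000
    promoter_downstream: int = 500
    keep_mito: bool = False
    liftover_min_fraction: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError("at least one peak file is required")
        if not self.blacklist:
            raise ValueError("a blacklist peak file is required")
        unknown = set(self.analyses) - set(ALL_ANALYSES)
        if unknown:
            raise ValueError(f"unknown analysis toggles: {sorted(unknown)}")

    def enabled(self, name: str) -> bool:
        return self.analyses.get(name, True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ReportBundle:
    config: RunConfig
    qc: pd.DataFrame
    tables: dict[str, pd.DataFrame]
    figures: dict[str, Path]
    skipped: dict[str, str]
    files_dir: Path
    html_path: Optional[Path] = None


def gather_files(directory, pattern: str = "**/*.narrowPeak") -> list[tuple[str, Path]]:
    """Recursively collect peak files matching a glob pattern.

    Labels are derived from the path relative to ``directory`` (suffix
    stripped, separators -> underscores); output order is deterministic
    lexicographic. An empty match emits a warning, not an error.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"{directory} is not a directory")
    matches = sorted(directory.glob(pattern))
    if not matches:
        warnings.warn(f"no files matching {pattern!r} under {directory}",
                      stacklevel=2)
    out = []
    for path in matches:
        rel = path.relative_to(directory)
        label = "_".join(rel.parts)
        for suffix in (".narrowPeak", ".broadPeak", ".bed", ".txt"):
            if label.endswith(suffix):
                label = label[: -len(suffix)]
                break
        out.append((label, path))
    return out


def _role_build(builds, role: str):
    if builds is None or isinstance(builds, str):
        return normalize_build(builds) if isinstance(builds, str) else None
    return normalize_build(builds.get(role, builds.get("peakfiles")))


def run(config: RunConfig) -> ReportBundle:
    """Execute the whole pipeline from a config; see module docstring."""
    outdir = Path(config.output_dir)
    files_dir = outdir / "peakcompare_files"
    files_dir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    skipped: dict[str, str] = {}
    tables: dict[str, pd.DataFrame] = {}
    figures: dict[str, Path] = {}

    def skip(name: str, reason: str) -> None:
        skipped[name] = reason
        logger.info("skipping %s: %s", name, reason)

    try:
        samples = [
            read_peaks(path, label=label,
                       genome_build=_role_build(config.builds, label)
                       or _role_build(config.builds, "peakfiles"))
            for label, path in config.peaks.items()]
        blacklist = read_peaks(config.blacklist, label="blacklist",
                               genome_build=_role_build(config.builds, "blacklist"))
        reference = None
        if config.reference:
            reference = read_peaks(config.reference, label="reference",
                                   genome_build=_role_build(config.builds, "reference")
                                   or _role_build(config.builds, "peakfiles"))
        chrom_sizes = (read_chrom_sizes(config.chrom_sizes)
                       if config.chrom_sizes else None)
        chains = [read_chain(p) for p in config.chains]
        dup_rates = {label: parse_picard_metrics(path)
                     for label, path in (config.picard or {}).items()}

        to_clean = samples + ([reference] if reference is not None else [])
        cleaned, metrics = standardize_all(
            to_clean, blacklist, builds=config.builds,
            target_build=config.target_build, chains=chains,
            chrom_sizes=chrom_sizes, keep_mito=config.keep_mito,
            liftover_min_fraction=config.liftover_min_fraction,
            duplication_rates=dup_rates)
        if reference is not None:
            reference = cleaned[-1]
            cleaned = cleaned[:-1]

        qc_rows = []
        for m in metrics:
            row = m.as_dict()
            row.update({f"width_{k}": v for k, v in row.pop("width_summary").items()})
            qc_rows.append(row)
        qc = pd.DataFrame(qc_rows)
        tables["qc_metrics"] = qc
    except Exception:
        logger.removeHandler(handler)
        handler.close()
        raise

    all_sets = cleaned + ([reference] if reference is not None else [])

    if config.enabled("upset"):
        if len(all_sets) < 2:
            skip("upset", "needs at least two peak sets")
        else:
            upset = upset_counts(all_sets)
            tables["upset_counts"] = upset.to_frame()
            figures["upset"] = plots.plot_upset(upset, files_dir / "upset.png")
    if len(all_sets) >= 2:
        om = overlap_matrix(all_sets)
        tables["overlap_matrix"] = om.to_frame().rename_axis("sample").reset_index()
        figures["overlap_matrix"] = plots.overlap_heatmap(
            om, files_dir / "overlap_matrix.png")
    else:
        skip("overlap_matrix", "needs at least two peak sets")

    if config.enabled("stat"):
        if reference is None:
            skip("stat", "no reference peak file supplied")
        else:
            splits = {}
            for ps in cleaned:
                try:
                    splits[ps.label] = stat_split(ps, reference)
                except ValueError as exc:
                    skip(f"stat[{ps.label}]", str(exc))
            if splits:
                tables["stat_split"] = pd.concat(
                    {label: s.to_frame() for label, s in splits.items()},
                    names=["sample"]).reset_index(level=0)
                figures["stat"] = plots.plot_stat(splits, files_dir / "stat.png")

    if config.enabled("precision_recall"):
        if reference is None:
            skip("precision_recall", "no reference peak file supplied")
        else:
            curves = {}
            for ps in cleaned:
                try:
                    curves[ps.label] = precision_recall(
                        ps, reference, n_thresholds=config.n_thresholds)
                except ValueError as exc:
                    skip(f"precision_recall[{ps.label}]", str(exc))
            if curves:
                tables["precision_recall"] = pd.concat(
                    {label: c.to_frame() for label, c in curves.items()},
                    names=["sample"]).reset_index(level=0)
                figures["precision_recall"] = plots.plot_precision_recall(
                    curves, files_dir / "precision_recall.png")

    if config.enabled("correlation"):
        if chrom_sizes is None:
            skip("correlation", "no chrom.sizes file supplied")
        elif len(all_sets) < 2:
            skip("correlation", "needs at least two peak sets")
        else:
            try:
                bins = rebin_peaks(all_sets, chrom_sizes,
                                   bin_width=config.bin_width)
                corr = compute_corr(bins, method=config.corr_method)
                tables["correlation"] = corr.to_frame().rename_axis(
                    "sample").reset_index()
                figures["correlation"] = plots.plot_corr(
                    corr, files_dir / "correlation.png")
            except ValueError as exc:
                skip("correlation", str(exc))

    seg = genes = gmt = None
    if config.segmentation:
        seg = read_segmentation(config.segmentation)
    if config.genes:
        genes = read_gene_bed(config.genes)
    if config.gmt:
        gmt = read_gmt(config.gmt)

    if config.enabled("chromhmm"):
        if seg is None:
            skip("chromhmm", "no segmentation file supplied")
        else:
            anns = {ps.label: chromhmm_annotate(ps, seg) for ps in cleaned}
            tables["chromhmm"] = pd.DataFrame(
                {label: a.fractions for label, a in anns.items()}
            ).rename_axis("state").reset_index()
            figures["chromhmm"] = plots.plot_chromhmm(
                anns, files_dir / "chromhmm.png")

    if config.enabled("feature"):
        if genes is None:
            skip("feature", "no gene model supplied")
        else:
            prom = (config.promoter_upstream, config.promoter_downstream)
            anns = {ps.label: feature_annotate(ps, genes, promoter=prom)
                    for ps in cleaned}
            tables["feature_annotation"] = pd.DataFrame(
                {label: a.fractions for label, a in anns.items()}
            ).rename_axis("feature").reset_index()
            figures["feature"] = plots.plot_features(
                anns, files_dir / "feature.png")

    if config.enabled("tss"):
        if genes is None:
            skip("tss", "no gene model supplied")
        else:
            profiles = {
                ps.label: tss_profile(ps, genes, window=config.tss_window,
                                      bin_width=config.tss_bin)
                for ps in cleaned}
            tables["tss_profile"] = pd.concat(
                {label: p.to_frame() for label, p in profiles.items()},
                names=["sample"]).reset_index(level=0)
            figures["tss"] = plots.plot_tss(profiles, files_dir / "tss.png")

    if config.enabled("enrichment"):
        if genes is None or gmt is None:
            skip("enrichment", "needs both a gene model and a GMT file")
        else:
            prom = (config.promoter_upstream, config.promoter_downstream)
            universe = genes.gene_ids()
            results = {}
            for ps in cleaned:
                query = peaks_to_genes(ps, genes, promoter=prom)
                if not query:
                    skip(f"enrichment[{ps.label}]", "no genes hit by peaks")
                    continue
                results[ps.label] = enrichment_test(query, gmt, universe)
            if results:
                tables["enrichment"] = pd.concat(
                    results, names=["sample"]).reset_index(level=0)
                figures["enrichment"] = plots.plot_enrichment(
                    results, files_dir / "enrichment.png")

    for name, frame in tables.items():
        frame.to_csv(files_dir / f"{name}.tsv", sep="\t", index=False,
                     float_format="%.6g")

    manifest = {
        "peakcompare_version": __version__,
        "generated": datetime.now().isoformat(timespec="seconds"),
        "config": config.to_dict(),
        "tables": sorted(tables),
        "skipped": skipped,
    }
    with open(outdir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, default=str)

    logger.info("run complete: %d tables, %d figures, %d skips",
                len(tables), len(figures), len(skipped))
    logger.removeHandler(handler)
    handler.close()

    bundle = ReportBundle(config=config, qc=qc, tables=tables,
                          figures=figures, skipped=skipped,
                          files_dir=files_dir)
    bundle.html_path = render_html(bundle, outdir / "report.html")
    return bundle


_PAGE = Template("""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>peakcompare report</title>
<style>
body { font-family: sans-serif; margin: 2em auto; max-width: 60em; }
nav ul { list-style: none; } table { border-collapse: collapse; }
td, th { border: 1px solid #ccc; padding: 3px 8px; font-size: 90%; }
img { max-width: 100%; } .skip { color: #888; font-style: italic; }
</style></head><body>
<h1>peakcompare report</h1>
<p>Generated $timestamp by peakcompare $version.</p>
<nav><ul>
<li><a href="#general-metrics">General Metrics</a></li>
<li><a href="#peak-overlap">Peak Overlap</a></li>
<li><a href="#functional-annotation">Functional Annotation</a></li>
</ul></nav>
$body
<details><summary>Run configuration</summary><pre>$config</pre></details>
</body></html>
""")


def _embed(path: Path) -> str:
    data = base64.b64encode(path.read_bytes()).decode("ascii")
    return f'<img src="data:image/png;base64,{data}" alt="{path.stem}">'


def render_html(bundle: ReportBundle, path=None) -> Path:
    """Render the bundle into one self-contained HTML file with a table
    of contents, embedded figures and a collapsed config echo."""
    sections = {
        "General Metrics": ["qc_metrics"],
        "Peak Overlap": ["upset_counts", "overlap_matrix", "stat_split",
                         "precision_recall", "correlation"],
        "Functional Annotation": ["chromhmm", "feature_annotation",
                                  "tss_profile", "enrichment"],
    }
    figure_of = {"upset_counts": "upset", "overlap_matrix": "overlap_matrix",
                 "stat_split": "stat", "precision_recall": "precision_recall",
                 "correlation": "correlation", "chromhmm": "chromhmm",
                 "feature_annotation": "feature", "tss_profile": "tss",
                 "enrichment": "enrichment"}
    parts = []
    for title, names in sections.items():
        anchor = title.lower().replace(" ", "-")
        parts.append(f'<h2 id="{anchor}">{title}</h2>')
        for name in names:
            parts.append(f"<h3>{name.replace('_', ' ')}</h3>")
            fig_key = figure_of.get(name)
            if fig_key and fig_key in bundle.figures:
                parts.append(_embed(bundle.figures[fig_key]))
            if name in bundle.tables:
                frame = bundle.tables[name]
                parts.append(frame.head(50).to_html(index=False,
                                                    float_format="%.4g"))
                if len(frame) > 50:
                    parts.append(f"<p class='skip'>({len(frame) - 50} more rows "
                                 f"in peakcompare_files/{name}.tsv)</p>")
            elif name not in bundle.figures:
                reason = bundle.skipped.get(name) or bundle.skipped.get(
                    figure_of.get(name, ""), "not computed")
                parts.append(f"<p class='skip'>skipped: {escape(str(reason))}</p>")

    path = Path(path) if path else bundle.files_dir.parent / "report.html"
    html = _PAGE.substitute(
        timestamp=datetime.now().isoformat(timespec="seconds"),
        version=__version__,
        body="\n".join(parts),
        config=escape(yaml.safe_dump(bundle.config.to_dict(), sort_keys=True)))
    path.write_text(html)
    return path
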