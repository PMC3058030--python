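"""One-shot analysis pipeline: filter -> presence -> peaks -> GMPA ->
significance curves -> clustering -> set cover (-> IPM), with per-stage TSV
outputs and a per-metal summary table.

Every stage writes a plain TSV so any stage can be re-run or inspected
independently; the whole run is deterministic for fixed inputs and
parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import clustering as clustering_mod
from . import gmpa, ipm, peaks as peaks_mod, setcover, significance
from .datamodel import Experiment, build_presence_matrix, filter_proteins, load_experiment

__all__ = ["RunConfig", "run_pipeline", "load_references"]

log = logging.getLogger("metallomap")

FLOAT_FORMAT = "%.10g"

SUMMARY_COLUMNS = [
    "metal",
    "known_subunits_total",
    "known_observed",
    "known_meeting_significance",
    "proteins_clustered",
    "clusters_total",
    "clusters_with_known",
    "cover_size",
    "uncovered_peaks",
]


@dataclass
class PeakDetectionParams:
    fold: float = 3.0
    window: int = 5
    min_len: int = 2


@dataclass
class ClusteringParams:
    min_cluster_size: int = 3
    deep_split: int = 2
    cut_height_fraction: float = 0.99


@dataclass
class IpmInputs:
    entries: str | None = None
    entries_format: str = "tsv"
    patterns: str | None = None
    curation: str | None = None
    matches: str | None = None


@dataclass
class RunConfig:
    fractions: str
    metals: str
    observations: str
    outdir: str
    peaks: str | None = None
    references: str | None = None
    ipm: IpmInputs = field(default_factory=IpmInputs)
    min_peptides: int = 2
    min_occurrences: int = 10
    default_ratio: float = 1.0
    peak_detection: PeakDetectionParams = field(default_factory=PeakDetectionParams)
    clustering: ClusteringParams = field(default_factory=ClusteringParams)
    setcover_candidates: str = "significant"  # or "all"
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        nested = {
            "peak_detection": PeakDetectionParams,
            "clustering": ClusteringParams,
            "ipm": IpmInputs,
        }
        kwargs = {}
        for key, sub_cls in nested.items():
            if key in data:
                sub = data.pop(key)
                unknown = set(sub) - set(sub_cls.__dataclass_fields__)
                if unknown:
                    raise ValueError(f"unknown key(s) in {key!r} block: {sorted(unknown)}")
                kwargs[key] = sub_cls(**sub)
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def load_references(path: str | Path) -> dict[str, set[str]]:
    """Known-metalloprotein reference list: TSV with metal, protein_id."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("metal", "protein_id") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    out: dict[str, set[str]] = {}
    for row in df.itertuples():
        out.setdefault(row.metal, set()).add(row.protein_id)
    return out


def _require(path: str | None, name: str) -> Path:
    if path is None:
        raise FileNotFoundError(f"pipeline input {name!r} is not configured")
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"pipeline input {name!r} not found: {p}")
    return p


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format=FLOAT_FORMAT)


def build_curves(
    scores: pd.DataFrame,
    references: dict[str, set[str]],
    min_occurrences: int = 10,
    default_ratio: float = 1.0,
) -> dict[str, significance.SignificanceCurve]:
    """Per-metal significance curves: reference-set where known
    metalloproteins qualify, extrapolated elsewhere, regression-ratio
    fallback when no metal has usable references."""
    metals = sorted(set(scores["metal"]))
    regressions: dict[str, tuple[float, float]] = {}
    curves: dict[str, significance.SignificanceCurve] = {}
    for metal in metals:
        sub = scores[scores["metal"] == metal]
        regressions[metal] = significance.fit_regression(sub)
        refs = references.get(metal, set())
        if refs:
            try:
                curves[metal] = significance.set_reference_curve(
                    sub, regressions[metal], refs, metal=metal, min_occurrences=min_occurrences
                )
            except ValueError:
                pass  # no qualifying reference; extrapolate below
    reference_curves = [c for c in curves.values() if c.source == "reference"]
    for metal in metals:
        if metal in curves:
            continue
        if reference_curves:
            curve = significance.extrapolate_curve(regressions[metal], reference_curves, metal=metal)
        else:
            curve = significance.manual_curve(metal, *regressions[metal], ratio_c=default_ratio)
        curves[metal] = curve
    return curves


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the output directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    exp: Experiment = load_experiment(
        _require(config.fractions, "fractions"),
        _require(config.metals, "metals"),
        _require(config.observations, "observations"),
    )
    log.info(
        "load: %d fractions, %d metal measurements, %d observation rows",
        len(exp.fractions), len(exp.metals), len(exp.observations),
    )

    observations = filter_proteins(exp.observations, min_peptides=config.min_peptides)
    n_before = exp.observations["protein_id"].nunique()
    n_after = observations["protein_id"].nunique()
    log.info("filter: min_peptides=%d, proteins %d -> %d", config.min_peptides, n_before, n_after)

    matrix = build_presence_matrix(observations, exp.fractions)
    log.info("presence: %d proteins x %d fractions", *matrix.shape)

    if config.peaks is not None:
        peaksets = peaks_mod.load_peak_regions(_require(config.peaks, "peaks"), exp.fractions)
        log.info("peaks: loaded curated regions for %d metals", len(peaksets))
    else:
        pd_params = config.peak_detection
        peaksets = {
            metal: peaks_mod.detect_peaks(
                exp.metals, exp.fractions, metal,
                fold=pd_params.fold, window=pd_params.window, min_len=pd_params.min_len,
            )
            for metal in sorted(set(exp.metals["metal"]))
        }
        log.info(
            "peaks: detected %d regions (fold=%g, window=%d)",
            sum(len(ps.regions) for ps in peaksets.values()), pd_params.fold, pd_params.window,
        )
    peaks_mod.write_peak_regions(peaksets, outdir / "peaks_used.tsv")

    scores = gmpa.score_all(matrix, peaksets)
    _write(scores, outdir / "gmpa_scores.tsv")
    log.info("gmpa: %d protein-metal scores over f=%d fractions", len(scores), matrix.shape[1])

    references = load_references(config.references) if config.references else {}
    curves = build_curves(
        scores, references,
        min_occurrences=config.min_occurrences, default_ratio=config.default_ratio,
    )
    significant: dict[str, set[str]] = {}
    for metal, curve in curves.items():
        sub = scores[scores["metal"] == metal]
        significant[metal] = significance.filter_significant(
            sub, curve, min_occurrences=config.min_occurrences
        )
    curve_frame = significance.curves_to_frame(
        [curves[m] for m in sorted(curves)], {m: len(s) for m, s in significant.items()}
    )
    _write(curve_frame, outdir / "significance.tsv")
    log.info(
        "significance: %s",
        ", ".join(f"{m}={len(significant[m])}" for m in sorted(significant)),
    )

    cluster_rows, core_rows, summary_rows, cover_rows = [], [], [], []
    cl = config.clustering
    for metal in sorted(curves):
        sig = significant[metal]
        refs = references.get(metal, set())
        observed_refs = refs & set(matrix.index)
        report = None
        if len(sig) >= 2:
            _, report = clustering_mod.build_report(
                matrix.loc[sorted(sig)], metal, peaks=peaksets.get(metal),
                min_cluster_size=cl.min_cluster_size, deep_split=cl.deep_split,
                cut_height_fraction=cl.cut_height_fraction,
            )
            for pid in sorted(report.assignments):
                cluster_rows.append(
                    {"metal": metal, "protein_id": pid, "cluster_label": report.assignments[pid]}
                )
            for lab in sorted(report.core_fractions):
                for fid in sorted(report.core_fractions[lab]):
                    core_rows.append({"metal": metal, "cluster_label": lab, "fraction_id": fid})
        candidates = sig if config.setcover_candidates == "significant" else set(matrix.index)
        metal_scores = dict(
            zip(scores.loc[scores["metal"] == metal, "protein_id"],
                scores.loc[scores["metal"] == metal, "score"])
        )
        cover = None
        if metal in peaksets and candidates:
            cover = setcover.greedy_cover(matrix, peaksets[metal], candidates, scores=metal_scores)
            newly: dict[str, int] = {}
            for peak, protein in cover.covered.items():
                newly[protein] = newly.get(protein, 0) + 1
            for rank, protein in enumerate(cover.chosen_proteins, start=1):
                cover_rows.append(
                    {"metal": metal, "rank": rank, "protein_id": protein,
                     "peaks_newly_covered": newly.get(protein, 0)}
                )
        clusters_with_known = 0
        if report is not None and refs:
            known_labels = {report.assignments[p] for p in refs & set(report.assignments) if report.assignments[p] > 0}
            clusters_with_known = len(known_labels)
        summary_rows.append(
            {
                "metal": metal,
                "known_subunits_total": len(refs),
                "known_observed": len(observed_refs),
                "known_meeting_significance": len(refs & sig),
                "proteins_clustered": len(sig) if report is not None else 0,
                "clusters_total": report.n_clusters if report is not None else 0,
                "clusters_with_known": clusters_with_known,
                "cover_size": cover.cover_size if cover is not None else 0,
                "uncovered_peaks": len(cover.uncovered_peaks) if cover is not None else 0,
            }
        )
    _write(pd.DataFrame(cluster_rows, columns=["metal", "protein_id", "cluster_label"]), outdir / "clusters.tsv")
    _write(pd.DataFrame(core_rows, columns=["metal", "cluster_label", "fraction_id"]), outdir / "cores.tsv")
    _write(
        pd.DataFrame(cover_rows, columns=["metal", "rank", "protein_id", "peaks_newly_covered"]),
        outdir / "cover.tsv",
    )
    summary = pd.DataFrame(summary_rows, columns=SUMMARY_COLUMNS)
    _write(summary, outdir / "summary.tsv")
    log.info("clustering/cover: %s",
             ", ".join(f"{r['metal']}:{r['clusters_total']}cl/{r['cover_size']}cov" for r in summary_rows))

    if config.ipm.entries and config.ipm.matches:
        entries = ipm.load_entries(_require(config.ipm.entries, "ipm.entries"), format=config.ipm.entries_format)
        patterns = (
            ipm.load_patterns(_require(config.ipm.patterns, "ipm.patterns"))
            if config.ipm.patterns
            else ipm.default_patterns()
        )
        curation = (
            pd.read_csv(_require(config.ipm.curation, "ipm.curation"), sep="\t", dtype=str, keep_default_na=False)
            if config.ipm.curation
            else None
        )
        matches = pd.read_csv(_require(config.ipm.matches, "ipm.matches"), sep="\t", dtype=str, keep_default_na=False)
        entry_metals = ipm.classify_entries(entries, patterns)
        predictions = ipm.predict_metal_proteins(entry_metals, curation, matches)
        _write(predictions, outdir / "predictions.tsv")
        log.info("ipm: %d entries, %d metal predictions", len(entries), len(predictions))

    return outdir
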