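"""Synthetic fractionation experiments with planted ground truth.

The generator emulates the structure of a native chromatographic
fractionation campaign measured by ICP-MS and MS/MS: several separations of
ordered fractions, per-metal replicate concentration traces with contiguous
rectangular peaks over a noisy lognormal baseline, and sparse Boolean-ish
protein occurrence with semi-quantitative peptide counts.  For each metal a
handful of *planted* metalloproteins preferentially occur inside that
metal's peak fractions; everything else is background.  The planted map is
returned as ground truth so every pipeline stage can be tested offline.

Defaults are sized like a desk-scale version of the motivating experiment
(8 separations x 60 fractions, 10 metals, 2 ICP-MS replicates, 5 planted
proteins per metal, 300 background proteins); :func:`paper_scale_config`
scales the same model up to ~2,600 fractions and ~870 proteins.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import DEFAULT_METALS, Experiment, write_experiment
from .peaks import PeakRegion, PeakSet, write_peak_regions

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "SynthResult",
    "generate",
    "write_dataset",
    "paper_scale_config",
    "paper_scale_fixture",
    "generate_coelution_matrix",
]

#: Same-metal peaks are placed at least this many fractions apart (and this
#: far from separation edges) so each peak is a distinct elution event with
#: an identifiable local baseline.
PEAK_GAP = 6
EDGE_MARGIN = 3


@dataclass
class SynthConfig:
    seed: int = 0
    n_separations: int = 8
    fractions_per_separation: int = 60
    metals: tuple[str, ...] = DEFAULT_METALS
    peaks_per_metal: int = 4
    peak_width_range: tuple[int, int] = (2, 5)
    baseline_mean: float = 1.0
    baseline_cv: float = 0.2
    peak_fold: float = 8.0
    n_replicates: int = 2
    planted_per_metal: int = 5
    p_hit: float = 0.8
    p_bg: float = 0.02
    n_background_proteins: int = 300
    bg_presence: float = 0.03
    peptide_lambda: float = 2.0
    single_peptide_fraction: float = 0.05

    def __post_init__(self) -> None:
        for name in ("p_hit", "p_bg", "bg_presence", "single_peptide_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.peak_width_range[0] < 2:
            raise ValueError("peak widths must be >= 2 (minimum peak size)")


@dataclass
class GroundTruth:
    planted: dict[str, str]  # protein_id -> metal
    peak_regions: dict[str, list[tuple[str, ...]]]  # metal -> fraction-id runs


@dataclass
class SynthResult:
    experiment: Experiment
    peaksets: dict[str, PeakSet]
    truth: GroundTruth
    config: SynthConfig = field(repr=False, default=None)


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _place_peaks(
    rng: np.random.Generator, config: SynthConfig, sep_ids: list[str]
) -> dict[str, list[tuple[str, int, int]]]:
    """Per metal: (separation_id, start, width) placements, non-overlapping
    with a gap for same-metal peaks within a separation."""
    w_lo, w_hi = config.peak_width_range
    F = config.fractions_per_separation
    if F < 2 * EDGE_MARGIN + w_hi:
        raise ValueError(
            f"infeasible peak placement: separations of {F} fractions cannot hold "
            f"a width-{w_hi} peak with {EDGE_MARGIN}-fraction edge margins"
        )
    placements: dict[str, list[tuple[str, int, int]]] = {}
    for metal in config.metals:
        placed: list[tuple[str, int, int]] = []
        occupied: dict[str, list[tuple[int, int]]] = {s: [] for s in sep_ids}
        attempts = 0
        while len(placed) < config.peaks_per_metal:
            attempts += 1
            if attempts > 1000 * config.peaks_per_metal:
                raise ValueError(
                    f"infeasible peak placement for {metal}: "
                    f"{config.peaks_per_metal} peaks do not fit with the required spacing"
                )
            sep = sep_ids[int(rng.integers(len(sep_ids)))]
            width = int(rng.integers(w_lo, w_hi + 1))
            start = int(rng.integers(EDGE_MARGIN, F - width - EDGE_MARGIN + 1))
            ok = all(
                start >= e + PEAK_GAP or start + width + PEAK_GAP <= s
                for s, e in occupied[sep]
            )
            if ok:
                occupied[sep].append((start, start + width))
                placed.append((sep, start, width))
        placements[metal] = sorted(placed)
    return placements


def generate(config: SynthConfig) -> SynthResult:
    """Generate a complete synthetic experiment; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    sep_ids = [f"S{i + 1:02d}" for i in range(config.n_separations)]
    F = config.fractions_per_separation
    frac_rows = []
    for sep in sep_ids:
        for k in range(F):
            frac_rows.append(
                {
                    "fraction_id": f"{sep}F{k:03d}",
                    "separation_id": sep,
                    "order_index": k,
                    "parent_fraction_id": ".",
                    "level": 2,
                }
            )
    fractions = pd.DataFrame(frac_rows)
    frac_ids = list(fractions["fraction_id"])
    frac_index = {f: i for i, f in enumerate(frac_ids)}
    n_frac = len(frac_ids)

    placements = _place_peaks(rng, config, sep_ids)
    peaksets: dict[str, PeakSet] = {}
    truth_regions: dict[str, list[tuple[str, ...]]] = {}
    for metal in config.metals:
        regions = []
        for sep, start, width in placements[metal]:
            member = tuple(f"{sep}F{k:03d}" for k in range(start, start + width))
            regions.append(PeakRegion(f"{metal}_{sep}_{start}", metal, sep, member))
        peaksets[metal] = PeakSet(metal, regions)
        truth_regions[metal] = [r.fraction_ids for r in regions]

    # ICP-MS traces: lognormal baseline, multiplied by peak_fold inside peaks
    mu, sigma = _lognormal_params(config.baseline_mean, config.baseline_cv)
    metal_rows = []
    for metal in config.metals:
        conc = rng.lognormal(mu, sigma, size=(config.n_replicates, n_frac))
        in_peak = np.zeros(n_frac, dtype=bool)
        for region in peaksets[metal].regions:
            for fid in region.fraction_ids:
                in_peak[frac_index[fid]] = True
        conc[:, in_peak] *= config.peak_fold
        for rep in range(config.n_replicates):
            for i, fid in enumerate(frac_ids):
                metal_rows.append(
                    {
                        "fraction_id": fid,
                        "metal": metal,
                        "replicate": rep + 1,
                        "concentration": conc[rep, i],
                    }
                )
    metals = pd.DataFrame(metal_rows)

    # proteins: planted metalloproteins then background, fixed draw order
    planted: dict[str, str] = {}
    protein_probs: list[tuple[str, np.ndarray, bool]] = []
    for metal in config.metals:
        peak_mask = np.zeros(n_frac, dtype=bool)
        for fid in peaksets[metal].peak_fraction_ids:
            peak_mask[frac_index[fid]] = True
        for i in range(config.planted_per_metal):
            pid = f"MP_{metal}_{i + 1:02d}"
            planted[pid] = metal
            probs = np.where(peak_mask, config.p_hit, config.p_bg)
            protein_probs.append((pid, probs, False))
    n_single = int(round(config.single_peptide_fraction * config.n_background_proteins))
    for i in range(config.n_background_proteins):
        pid = f"BG_{i + 1:04d}"
        probs = np.full(n_frac, config.bg_presence)
        protein_probs.append((pid, probs, i < n_single))
    obs_rows = []
    for pid, probs, single_peptide in protein_probs:
        present = rng.random(n_frac) < probs
        counts = 1 + rng.poisson(config.peptide_lambda, size=n_frac)
        if single_peptide:
            counts = np.ones(n_frac, dtype=int)
        for i in np.flatnonzero(present):
            obs_rows.append(
                {
                    "fraction_id": frac_ids[i],
                    "protein_id": pid,
                    "peptide_count": int(counts[i]),
                }
            )
    observations = pd.DataFrame(obs_rows, columns=["fraction_id", "protein_id", "peptide_count"])
    experiment = Experiment(fractions, metals, observations)
    return SynthResult(experiment, peaksets, GroundTruth(planted, truth_regions), config)


def write_dataset(result: SynthResult, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle as the standard TSV formats plus truth and config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = write_experiment(result.experiment, outdir)
    paths["peaks"] = outdir / "peaks.tsv"
    write_peak_regions(result.peaksets, paths["peaks"])
    truth = pd.DataFrame(
        sorted(result.truth.planted.items()), columns=["protein_id", "metal"]
    )
    paths["truth"] = outdir / "truth.tsv"
    truth.to_csv(paths["truth"], sep="\t", index=False, lineterminator="\n")
    paths["config"] = outdir / "synth_config.json"
    cfg = asdict(result.config) if result.config is not None else {}
    paths["config"].write_text(json.dumps(cfg, indent=2, default=list) + "\n")
    return paths


def paper_scale_config(seed: int = 0) -> SynthConfig:
    """Preset sized like the motivating study: ~2,600 fractions, 870 proteins."""
    return SynthConfig(
        seed=seed,
        n_separations=43,
        fractions_per_separation=60,
        n_background_proteins=820,
    )


def paper_scale_fixture(seed: int = 0) -> SynthResult:
    return generate(paper_scale_config(seed))


def generate_coelution_matrix(
    seed: int,
    n_groups: int = 10,
    proteins_per_group: int = 5,
    n_fractions: int = 400,
    support_size: int = 12,
    p_hit: float = 0.9,
    p_bg: float = 0.02,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Boolean presence matrix with planted, well-separated co-elution groups.

    Fractions are split into ``n_groups`` equal segments; each group's
    support is a random contiguous block of ``support_size`` fractions
    within its own segment, so supports are disjoint.  Group members are
    present in their support with ``p_hit`` and elsewhere with ``p_bg``.
    Returns the matrix and the true group label per protein.
    """
    if n_fractions < n_groups * support_size:
        raise ValueError("not enough fractions for disjoint group supports")
    rng = np.random.default_rng(seed)
    frac_ids = [f"S01F{k:03d}" for k in range(n_fractions)]
    seg = n_fractions // n_groups
    rows = {}
    labels = {}
    for g in range(n_groups):
        start = g * seg + int(rng.integers(0, seg - support_size + 1))
        support = np.zeros(n_fractions, dtype=bool)
        support[start : start + support_size] = True
        for j in range(proteins_per_group):
            pid = f"G{g + 1:02d}_P{j + 1:02d}"
            probs = np.where(support, p_hit, p_bg)
            rows[pid] = rng.random(n_fractions) < probs
            labels[pid] = g + 1
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=frac_ids)
    matrix = matrix.sort_index(kind="mergesort")
    matrix.index.name = "protein_id"
    matrix.columns.name = "fraction_id"
    return matrix, labels
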