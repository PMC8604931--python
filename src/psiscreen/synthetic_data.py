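"""Synthetic two-class PSI-MS-like cohorts with known ground truth.

The generator emulates the design of a small case-control ambient-MS study:
10 + 10 subjects, triplicate spectra per subject, a unit-resolution m/z grid
of 950 variables (50-1000 Th), a smooth polynomial baseline with per-subject
jitter, a set of peaks shared by everyone, and a small set of
class-discriminative peaks at canonical positions.  Subject-level peak
heights are lognormal; replicates of one subject blend a shared noise field
with fresh noise according to ``within_subject_corr``; the case class is
shifted at each discriminative bin by a stated effect size Delta expressed
in within-class standard-deviation units, calibrated against the realized
no-effect cohort so that the planted standardized mean difference is
unambiguous.  Every draw is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .spectra_io import PeakList, SpectraMatrix, bin_peaklists

__all__ = [
    "CANONICAL_DISCRIMINATIVE_MZ",
    "DEFAULT_SHARED_PEAKS",
    "CohortConfig",
    "CohortTruth",
    "generate_cohort",
    "make_null_cohort",
    "empirical_smd",
]

# Unit-resolution variables repeatedly flagged by selection models in this
# kind of screening data; the generator plants its effects at a subset.
CANONICAL_DISCRIMINATIVE_MZ = (65.0, 77.0, 118.0, 173.0, 360.0, 390.0, 475.0)


def _default_shared_peaks(n: int = 40, seed: int = 987321) -> tuple:
    """Fixed catalogue of shared (m/z, mean height, CV) peaks."""
    rng = np.random.default_rng(seed)
    candidates = [v for v in range(55, 996) if float(v) not in CANONICAL_DISCRIMINATIVE_MZ]
    positions = sorted(rng.choice(candidates, size=n, replace=False).tolist())
    heights = rng.uniform(20.0, 200.0, size=n)
    return tuple((float(p), float(h), 0.25) for p, h in zip(positions, heights))


DEFAULT_SHARED_PEAKS = _default_shared_peaks()


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of a synthetic cohort.

    Defaults mirror the target design: 10 subjects per class, triplicates,
    950 unit-resolution bins, and two discriminative peaks of effect size
    Delta = 5 within-class SD at m/z 118 and 77.
    """

    n_subjects_per_class: int = 10
    replicates: int = 3
    mz_min: float = 50.0
    mz_max: float = 1000.0
    bin_width: float = 1.0
    shared_peaks: tuple = DEFAULT_SHARED_PEAKS  # (mz, mean height, CV)
    discriminative_peaks: tuple = ((118.0, 5.0, +1), (77.0, 5.0, +1))  # (mz, Delta, dir)
    disc_height: float = 60.0  # base mean height of discriminative peaks
    disc_cv: float = 0.3
    baseline_coeffs: tuple = (25.0, -30.0, 15.0)  # polynomial in t = scaled m/z
    baseline_jitter: float = 0.1  # per-subject multiplicative SD on the drift
    noise_sd: float = 1.0  # additive per-bin Gaussian SD
    mult_cv: float = 0.1  # per-replicate multiplicative height jitter
    within_subject_corr: float = 0.7
    off_center: bool = False  # place peaks off bin centers (binning edge cases)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects_per_class < 1 or self.replicates < 1:
            raise ValueError("need at least one subject and one replicate")
        if not 0.0 <= self.within_subject_corr < 1.0:
            raise ValueError("within_subject_corr must lie in [0, 1)")
        for mz, delta, _ in self.discriminative_peaks:
            if delta < 0:
                raise ValueError("effect sizes must be non-negative")


@dataclass
class CohortTruth:
    """Ground truth recorded alongside a generated cohort."""

    labels: dict[str, str]  # subject -> class
    discriminative_mz: list[float]
    injected_shift: dict[float, float]  # m/z -> absolute intensity shift
    baselines: np.ndarray  # n_spectra x n_variables drift (noise-free)
    shared_mz: list[float]
    seed: int


def _baseline_rows(cfg: CohortConfig, axis: np.ndarray, scale: np.ndarray) -> np.ndarray:
    t = (axis - cfg.mz_min) / (cfg.mz_max - cfg.mz_min)
    base = np.polynomial.polynomial.polyval(t, np.asarray(cfg.baseline_coeffs))
    return np.outer(scale, base)


def generate_cohort(cfg: CohortConfig | None = None) -> tuple[SpectraMatrix, CohortTruth]:
    """Draw one synthetic cohort; returns the matrix plus its ground truth.

    The discriminative shift is injected after the no-effect cohort is
    realized: the pooled within-class SD of the subject-averaged intensity at
    each planted bin is measured, and ``direction * Delta * SD`` is added to
    every replicate of every case subject at that bin.  Adding a constant
    leaves the within-class SD unchanged, so the planted standardized mean
    difference equals Delta up to sampling noise.
    """
    cfg = cfg or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    n_per = cfg.n_subjects_per_class
    subjects = [f"C{i + 1:02d}" for i in range(n_per)] + [
        f"F{i + 1:02d}" for i in range(n_per)
    ]
    labels = {s: ("control" if s.startswith("C") else "case") for s in subjects}

    peaks = [(mz, h, cv) for mz, h, cv in cfg.shared_peaks]
    peaks += [(mz, cfg.disc_height, cfg.disc_cv) for mz, _, _ in cfg.discriminative_peaks]
    peak_mz = np.array([p[0] for p in peaks])
    peak_mean = np.array([p[1] for p in peaks])
    peak_cv = np.array([p[2] for p in peaks])
    # Per-cohort position offsets: zero by default (peaks at exact grid
    # centers so ground-truth bins are unambiguous), uniform otherwise.
    # Peak m/z values in the config are bin lower edges.
    if cfg.off_center:
        offsets = rng.uniform(-0.49, 0.49, size=peak_mz.size)
    else:
        offsets = np.zeros(peak_mz.size)
    centers = peak_mz + (0.5 + offsets) * cfg.bin_width
    # Gaussian-shaped peak: three sub-centroids inside one bin width.
    sub_off = np.array([-0.22, 0.0, 0.22]) * cfg.bin_width
    sub_w = np.array([0.2, 0.6, 0.2])

    sigma_ln = np.sqrt(np.log1p(peak_cv**2))
    rho = cfg.within_subject_corr

    peaklists: list[PeakList] = []
    spectrum_ids: list[str] = []
    subject_of: dict[str, str] = {}
    baseline_scale: list[float] = []
    noise_rows: list[np.ndarray] = []
    n_bins = int(np.floor((cfg.mz_max - cfg.mz_min) / cfg.bin_width + 1e-9))
    for subj in subjects:
        h_subj = peak_mean * np.exp(
            rng.normal(0.0, 1.0, size=peak_mz.size) * sigma_ln - sigma_ln**2 / 2
        )
        b_scale = max(1.0 + rng.normal(0.0, cfg.baseline_jitter), 0.0)
        eta_subj = rng.normal(0.0, 1.0, size=n_bins)
        for r in range(cfg.replicates):
            h_rep = np.maximum(h_subj * (1.0 + rng.normal(0.0, cfg.mult_cv,
                                                          size=peak_mz.size)), 0.0)
            pos = (centers[:, None] + sub_off[None, :]).ravel()
            inten = (h_rep[:, None] * sub_w[None, :]).ravel()
            order = np.argsort(pos, kind="stable")
            pos, inten = pos[order], inten[order]
            keep = np.concatenate([[True], np.diff(pos) > 0])  # guard exact ties
            sid = f"{subj}_r{r + 1}"
            peaklists.append(PeakList(pos[keep], inten[keep], source_id=sid))
            spectrum_ids.append(sid)
            subject_of[sid] = subj
            baseline_scale.append(b_scale)
            eta_rep = rng.normal(0.0, 1.0, size=n_bins)
            noise_rows.append(np.sqrt(rho) * eta_subj + np.sqrt(1.0 - rho) * eta_rep)

    m = bin_peaklists(peaklists, cfg.mz_min, cfg.mz_max, cfg.bin_width,
                      spectrum_ids=spectrum_ids, subject_of=subject_of,
                      class_of=labels)
    baselines = _baseline_rows(cfg, m.mz_axis, np.array(baseline_scale))
    X = m.X + baselines + cfg.noise_sd * np.array(noise_rows)
    X = np.maximum(X, 0.0)

    # Inject the class effect, calibrated on the realized no-effect cohort.
    y = np.array([labels[subject_of[sid]] for sid in spectrum_ids])
    subj_per_row = np.array([subject_of[sid] for sid in spectrum_ids])
    injected: dict[float, float] = {}
    for mz, delta, direction in cfg.discriminative_peaks:
        if delta == 0:
            injected[float(mz)] = 0.0
            continue
        label = float(mz) if cfg.bin_width == 1.0 else mz + cfg.bin_width / 2.0
        try:
            col = m.column_index(label)
        except KeyError as exc:
            raise ValueError(f"discriminative m/z {mz} is not on the grid") from exc
        subj_means = {s: X[subj_per_row == s, col].mean() for s in subjects}
        sds = []
        for cls in ("control", "case"):
            vals = [subj_means[s] for s in subjects if labels[s] == cls]
            sds.append(np.var(vals, ddof=1))
        sd_within = float(np.sqrt(np.mean(sds)))
        shift = direction * delta * sd_within
        X[y == "case", col] = np.maximum(X[y == "case", col] + shift, 0.0)
        injected[float(mz)] = float(shift)

    matrix = SpectraMatrix(X, m.mz_axis, spectrum_ids, subject_of, labels)
    truth = CohortTruth(
        labels=labels,
        discriminative_mz=[float(mz) for mz, d, _ in cfg.discriminative_peaks if d > 0],
        injected_shift=injected,
        baselines=baselines,
        shared_mz=[p[0] for p in cfg.shared_peaks],
        seed=cfg.seed,
    )
    return matrix, truth


def make_null_cohort(cfg: CohortConfig | None = None) -> tuple[SpectraMatrix, CohortTruth]:
    """Negative control: all effect sizes forced to zero, labels still assigned."""
    cfg = cfg or CohortConfig()
    nulled = tuple((mz, 0.0, d) for mz, _, d in cfg.discriminative_peaks)
    return generate_cohort(replace(cfg, discriminative_peaks=nulled))


def empirical_smd(m: SpectraMatrix, mz: float) -> float:
    """Standardized mean difference (case - control) of the subject-averaged
    intensity at one grid variable, pooled within-class SD in the denominator."""
    col = m.column_index(mz)
    subj_per_row = m.subject_ids_per_row()
    means: dict[str, list[float]] = {"control": [], "case": []}
    for subj in m.subjects:
        val = float(m.X[subj_per_row == subj, col].mean())
        means[m.class_of[subj]].append(val)
    diff = np.mean(means["case"]) - np.mean(means["control"])
    pooled = np.sqrt((np.var(means["case"], ddof=1) + np.var(means["control"], ddof=1)) / 2)
    return float(diff / pooled)
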