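"""Synthetic-data generators for every input the toolkit consumes.

No public dataset exists for this kind of rare-cell workflow, so the
package ships generators with known ground truth:

* :func:`render_field` — multi-channel immunofluorescence fields with
  stained cell populations (tumor-like, leukocyte-like, debris), tumor-cell
  clusters, a multiplicative illumination gradient and additive noise;
* :func:`sample_feature_table` — labeled per-cell feature tables drawn from
  class-conditional distributions on log-intensity / logit-shape scales;
* :func:`simulate_cohort` — per-subject CTC counts (zero-inflated negative
  binomial) with recurrence outcomes, calibrated per clinical group;
* :func:`spike_in_experiment` — binomial recovery of spiked cells;
* :func:`simulate_bin_counts` — negative-binomial genomic bin counts from a
  ground-truth copy-number profile with a quadratic GC response.

Every generator is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .imaging import FluorescentField
from .schema import (
    CHANNELS,
    FEATURE_COLUMNS,
    LABEL_COLUMN,
    NEGATIVE_LABEL,
    POSITIVE_LABEL,
)

__all__ = [
    "FieldSpec",
    "PopulationSpec",
    "ClassParams",
    "CohortSpec",
    "GroupSpec",
    "GroundTruthCN",
    "DEFAULT_INTENSITY_SPEC",
    "DEFAULT_RADIUS_SPEC",
    "DEFAULT_COHORT_SPEC",
    "render_field",
    "sample_feature_table",
    "simulate_cohort",
    "spike_in_experiment",
    "simulate_bin_counts",
    "zinb_positive_prob",
    "default_population_spec",
    "toy_genome_bins",
    "default_cn_truth",
]

# --------------------------------------------------------------------------
# Fluorescent fields
# --------------------------------------------------------------------------

#: Per-class, per-channel (mean, sd) of cell amplitude above baseline, in
#: 16-bit camera counts.  Tumor-like cells are DAPI+/CK+/CD45−, leukocytes
#: DAPI+/CK−/CD45+, debris DAPI-absent with faint channel bleed.
DEFAULT_INTENSITY_SPEC: dict[str, dict[str, tuple[float, float]]] = {
    "CTC": {"dapi": (20000.0, 3000.0), "ck": (18000.0, 3000.0), "cd45": (0.0, 0.0)},
    "WBC": {"dapi": (15000.0, 2500.0), "ck": (0.0, 0.0), "cd45": (15000.0, 2500.0)},
    "debris": {"dapi": (0.0, 0.0), "ck": (2500.0, 800.0), "cd45": (2500.0, 800.0)},
}

#: Per-class (mean, sd) cell radius in µm.  Nominal radii are set so that
#: the area measured inside an Otsu mask of the Gaussian blob (which cuts
#: at roughly a third of peak amplitude, i.e. ~0.7 of the nominal radius)
#: lands in the physiological range.  Debris is sub-cellular.
DEFAULT_RADIUS_SPEC: dict[str, tuple[float, float]] = {
    "CTC": (6.5, 0.5),
    "WBC": (5.5, 0.4),
    "debris": (1.2, 0.3),
}


@dataclass(frozen=True)
class FieldSpec:
    """Recipe for one simulated fluorescence field.

    ``illumination_gradient`` is the amplitude of a multiplicative linear
    shading field applied to the stain signal (0 = flat illumination);
    ``cluster_spec`` lists sizes of deliberately adjacent tumor-cell
    clusters, drawn from the ``n_ctc`` budget.
    """

    width: int = 1200
    height: int = 1200
    pixel_size: float = 0.5
    n_wbc: int = 100
    n_ctc: int = 5
    n_debris: int = 20
    cluster_spec: tuple[int, ...] = ()
    illumination_gradient: float = 0.15
    noise_sd: float = 30.0
    baseline: float = 500.0
    intensity_spec: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: DEFAULT_INTENSITY_SPEC
    )
    cell_radius_spec: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: DEFAULT_RADIUS_SPEC
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("field dimensions must be positive")
        if min(self.n_wbc, self.n_ctc, self.n_debris) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.illumination_gradient < 0:
            raise ValueError("illumination_gradient must be >= 0")
        if any(s < 2 for s in self.cluster_spec):
            raise ValueError("clusters need at least 2 cells")
        if sum(self.cluster_spec) > self.n_ctc:
            raise ValueError("cluster_spec exceeds the CTC budget")
        for cls, chans in self.intensity_spec.items():
            for ch, (m, _s) in chans.items():
                if m < 0:
                    raise ValueError(f"negative intensity mean for {cls}/{ch}")


def illumination_field(spec: FieldSpec) -> np.ndarray:
    """The multiplicative shading field the generator applies: a linear
    tilt along x of amplitude ``illumination_gradient`` around 1."""
    x = np.linspace(-0.5, 0.5, spec.width)
    plane = 1.0 + spec.illumination_gradient * x
    return np.clip(np.broadcast_to(plane, (spec.height, spec.width)), 0.05, None).copy()


def _place_nonoverlapping(
    rng: np.random.Generator,
    radii: Sequence[float],
    width: int,
    height: int,
    existing: list[tuple[float, float, float]],
    max_retries: int = 100,
) -> list[tuple[float, float]]:
    """Rejection-sample centers so that no two objects overlap (centers at
    least the sum of radii + 1 px apart)."""
    placed = []
    for r in radii:
        ok = False
        for _ in range(max_retries):
            x = rng.uniform(r, width - r)
            y = rng.uniform(r, height - r)
            if all(
                (x - ex) ** 2 + (y - ey) ** 2 >= (r + er + 1.0) ** 2
                for ex, ey, er in existing
            ):
                ok = True
                break
        if not ok:
            raise RuntimeError(
                "non-overlap placement failed after "
                f"{max_retries} retries: field too crowded"
            )
        existing.append((x, y, r))
        placed.append((x, y))
    return placed


def _add_blob(img: np.ndarray, x: float, y: float, radius_px: float,
              amplitude: float) -> None:
    """Add an isotropic Gaussian blob (σ = radius/2) truncated at 3σ."""
    if amplitude <= 0:
        return
    sigma = radius_px / 2.0
    half = int(math.ceil(3.0 * sigma))
    h, w = img.shape
    r0, r1 = max(0, int(y) - half), min(h, int(y) + half + 1)
    c0, c1 = max(0, int(x) - half), min(w, int(x) + half + 1)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    d2 = (yy - y) ** 2 + (xx - x) ** 2
    blob = amplitude * np.exp(-d2 / (2.0 * sigma**2))
    blob[d2 > (3.0 * sigma) ** 2] = 0.0
    img[r0:r1, c0:c1] += blob


def render_field(spec: FieldSpec) -> tuple[FluorescentField, pd.DataFrame]:
    """Render a field and its per-object ground truth.

    Each placed cell is a radially decaying Gaussian blob with
    class-dependent per-channel amplitudes.  Singleton cells are placed
    without overlap; clustered tumor cells are placed adjacent/overlapping
    around a shared anchor.  The illumination gradient multiplies the stain
    signal, the camera baseline is added, and Gaussian read noise is added
    last; pixel values are clipped to the 16-bit range and quantized.

    Returns
    -------
    field, truth
        The rendered :class:`~rarecell.imaging.FluorescentField` and a
        DataFrame with one row per placed object (center, radius, class,
        cluster id, per-channel amplitudes).
    """
    rng = np.random.default_rng(spec.seed)
    w, h = spec.width, spec.height
    px = spec.pixel_size

    records: list[dict] = []
    existing: list[tuple[float, float, float]] = []

    def draw_radius(cls: str) -> float:
        m, s = spec.cell_radius_spec[cls]
        return max(0.5, rng.normal(m, s)) / px  # px

    def draw_amps(cls: str) -> dict[str, float]:
        out = {}
        for ch in CHANNELS:
            m, s = spec.intensity_spec[cls].get(ch, (0.0, 0.0))
            out[ch] = max(0.0, rng.normal(m, s)) if (m > 0 or s > 0) else 0.0
        return out

    # clusters first: anchor placed without overlap against other groups,
    # members deliberately adjacent around it
    n_clustered = sum(spec.cluster_spec)
    for cid, size in enumerate(spec.cluster_spec):
        r0 = draw_radius("CTC")
        (ax, ay), = _place_nonoverlapping(rng, [r0 * (1 + size)], w, h, existing)
        existing.pop()  # reserve region, members re-registered below
        angle0 = rng.uniform(0, 2 * np.pi)
        for j in range(size):
            r = draw_radius("CTC")
            if j == 0:
                x, y = ax, ay
            else:
                ang = angle0 + 2 * np.pi * j / size
                d = 1.4 * r  # touching/overlapping neighbours
                x, y = ax + d * math.cos(ang), ay + d * math.sin(ang)
                x = min(max(x, r), w - r)
                y = min(max(y, r), h - r)
            existing.append((x, y, r))
            records.append(
                {"x": x, "y": y, "radius_px": r, "radius_um": r * px,
                 "cell_class": "CTC", "cluster_id": cid, **{
                     f"amp_{ch}": a for ch, a in draw_amps("CTC").items()}}
            )

    for cls, n in (("CTC", spec.n_ctc - n_clustered), ("WBC", spec.n_wbc),
                   ("debris", spec.n_debris)):
        radii = [draw_radius(cls) for _ in range(n)]
        centers = _place_nonoverlapping(rng, radii, w, h, existing)
        for (x, y), r in zip(centers, radii):
            records.append(
                {"x": x, "y": y, "radius_px": r, "radius_um": r * px,
                 "cell_class": cls, "cluster_id": None, **{
                     f"amp_{ch}": a for ch, a in draw_amps(cls).items()}}
            )

    truth = pd.DataFrame(
        records,
        columns=["x", "y", "radius_px", "radius_um", "cell_class", "cluster_id"]
        + [f"amp_{ch}" for ch in CHANNELS],
    )

    illum = illumination_field(spec)
    channels = {}
    for ch in CHANNELS:
        signal = np.zeros((h, w), dtype=float)
        for rec in records:
            _add_blob(signal, rec["x"], rec["y"], rec["radius_px"], rec[f"amp_{ch}"])
        img = spec.baseline + signal * illum
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
        channels[ch] = np.clip(np.round(img), 0, 65535)
    return FluorescentField(channels, pixel_size=px), truth


# --------------------------------------------------------------------------
# Labeled feature tables
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassParams:
    """Class-conditional feature distributions, parameterized on scales
    where positivity constraints hold by construction: log for intensity
    folds and areas, logit for shape parameters in (0, 1)."""

    log_fold: Mapping[str, tuple[float, float]]       # channel -> (mean, sd)
    log_area: tuple[float, float]                     # log µm²
    logit_eccentricity: tuple[float, float]
    logit_solidity: tuple[float, float]
    logit_form_factor: tuple[float, float]


@dataclass(frozen=True)
class PopulationSpec:
    """Two-class cell population for classifier experiments.

    ``separation`` rescales the distance between the class mean vectors
    around their midpoint: 0 makes the classes exchangeable, 1 keeps the
    defaults (≥ 6 sd apart on the marker channels).
    """

    prevalence: float = 0.10
    separation: float = 1.0
    classes: Mapping[str, ClassParams] = field(default_factory=dict)
    background: float = 500.0

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        for cls, p in self.classes.items():
            for name, (_m, s) in list(p.log_fold.items()) + [
                ("log_area", p.log_area),
                ("ecc", p.logit_eccentricity),
                ("sol", p.logit_solidity),
                ("ff", p.logit_form_factor),
            ]:
                if s < 0:
                    raise ValueError(f"negative sd for {cls}/{name}")
                if s == 0 and self.separation == 0:
                    warnings.warn(
                        f"degenerate spec: zero variance for {cls}/{name} "
                        "with separation 0"
                    )


def default_population_spec(
    prevalence: float = 0.10, separation: float = 1.0
) -> PopulationSpec:
    """Default two-class population: tumor-like cells bright in CK and dim
    in CD45, leukocytes the reverse; both nucleated.  Fold distributions
    match what the image pipeline measures on rendered fields (annulus
    backgrounds sit on the blob tail, compressing folds to single digits).
    At ``separation=1`` each marker channel separates the classes by ≥ 6
    within-class sd on the log scale."""
    log = math.log
    classes = {
        POSITIVE_LABEL: ClassParams(
            log_fold={"dapi": (log(4.5), 0.2), "ck": (log(4.5), 0.2),
                      "cd45": (log(1.0), 0.1)},
            log_area=(log(95.0), 0.20),
            logit_eccentricity=(0.0, 0.5),
            logit_solidity=(2.6, 0.4),
            logit_form_factor=(1.7, 0.4),
        ),
        NEGATIVE_LABEL: ClassParams(
            log_fold={"dapi": (log(3.5), 0.2), "ck": (log(1.0), 0.1),
                      "cd45": (log(3.5), 0.2)},
            log_area=(log(50.0), 0.15),
            logit_eccentricity=(-0.2, 0.5),
            logit_solidity=(2.8, 0.4),
            logit_form_factor=(1.9, 0.4),
        ),
    }
    return PopulationSpec(prevalence=prevalence, separation=separation,
                          classes=classes)


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def sample_feature_table(
    spec: PopulationSpec | None = None, n: int = 4000, seed: int = 0
) -> pd.DataFrame:
    """Draw a labeled cell-feature table with the image-pipeline schema.

    Labels are drawn at the stated prevalence; features come from the
    class-conditional distributions with the class means pulled toward
    their midpoint by the separation scale.
    """
    if spec is None:
        spec = default_population_spec()
    if n < 2:
        raise ValueError("n must be at least 2")
    rng = np.random.default_rng(seed)
    labels = np.where(rng.random(n) < spec.prevalence, POSITIVE_LABEL, NEGATIVE_LABEL)
    if len(set(labels)) < 2:
        # force both classes representable
        labels[0] = POSITIVE_LABEL
        labels[1] = NEGATIVE_LABEL

    names = list(spec.classes)
    if len(names) != 2:
        raise ValueError("PopulationSpec needs exactly two classes")

    def sep_mean(attr_means: dict[str, float]) -> dict[str, float]:
        center = sum(attr_means.values()) / 2.0
        return {c: center + spec.separation * (m - center)
                for c, m in attr_means.items()}

    # precompute separation-adjusted means for every scalar parameter
    fold_means = {
        ch: sep_mean({c: spec.classes[c].log_fold[ch][0] for c in names})
        for ch in CHANNELS
    }
    area_means = sep_mean({c: spec.classes[c].log_area[0] for c in names})
    ecc_means = sep_mean({c: spec.classes[c].logit_eccentricity[0] for c in names})
    sol_means = sep_mean({c: spec.classes[c].logit_solidity[0] for c in names})
    ff_means = sep_mean({c: spec.classes[c].logit_form_factor[0] for c in names})

    cols: dict[str, np.ndarray] = {}
    bg = spec.background
    area = np.empty(n)
    for c in names:
        idx = labels == c
        k = int(idx.sum())
        p = spec.classes[c]
        area[idx] = np.exp(rng.normal(area_means[c], p.log_area[1], k))
    area_px = area / (0.5**2)  # nominal 0.5 µm/px, for integrated intensity
    cols["area_um2"] = area
    ecc = np.empty(n)
    sol = np.empty(n)
    ff = np.empty(n)
    for c in names:
        idx = labels == c
        k = int(idx.sum())
        p = spec.classes[c]
        ecc[idx] = _expit(rng.normal(ecc_means[c], p.logit_eccentricity[1], k))
        sol[idx] = _expit(rng.normal(sol_means[c], p.logit_solidity[1], k))
        ff[idx] = _expit(rng.normal(ff_means[c], p.logit_form_factor[1], k))
    cols["eccentricity"] = ecc
    cols["solidity"] = sol
    cols["form_factor"] = ff
    cols["equiv_diameter_um"] = 2.0 * np.sqrt(area / np.pi)
    cols["perimeter_um"] = np.pi * cols["equiv_diameter_um"] / np.sqrt(ff)

    for ch in CHANNELS:
        fold = np.empty(n)
        for c in names:
            idx = labels == c
            k = int(idx.sum())
            sd = spec.classes[c].log_fold[ch][1]
            fold[idx] = np.exp(rng.normal(fold_means[ch][c], sd, k))
        mean = bg * fold
        cols[f"{ch}_fold"] = fold
        cols[f"{ch}_mean"] = mean
        cols[f"{ch}_median"] = mean * rng.normal(0.97, 0.01, n)
        cols[f"{ch}_max"] = mean * np.abs(rng.normal(1.6, 0.1, n))
        cols[f"{ch}_integrated"] = mean * area_px
        cols[f"{ch}_corr_mean"] = np.maximum(mean - bg, 0.0)

    table = pd.DataFrame(cols)[list(FEATURE_COLUMNS)]
    table[LABEL_COLUMN] = labels
    return table


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSpec:
    """Count and outcome model for one clinical group.

    CTC counts follow a zero-inflated negative binomial with structural
    zero probability ``pi``, NB mean ``mu`` and dispersion ``k`` (variance
    µ + µ²/k).  When ``hazard`` is set, recurrence times are exponential
    with that monthly hazard for count-0 subjects and ``hazard`` ×
    ``hazard_ratio_pos`` for count-positive subjects, censored at a uniform
    draw from the censoring window.
    """

    pi: float = 0.0
    mu: float = 1.0
    k: float = 1.0
    hazard: float | None = None
    hazard_ratio_pos: float = 1.0
    log10_afp: tuple[float, float] | None = None  # serum AFP, log10 ng/mL

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must be in [0, 1]")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.k <= 0:
            raise ValueError("k must be > 0")


@dataclass(frozen=True)
class CohortSpec:
    groups: Mapping[str, GroupSpec]
    censor_window: tuple[float, float] = (6.0, 33.0)  # months


#: Per-group NB parameters calibrated so that the closed-form positivity
#: (count >= 1) and mean match the clinical summaries this generator
#: emulates (e.g. HCC: positivity 59.3%, mean 1.37).  All groups fit with
#: pi = 0; healthy donors are effectively Poisson.
DEFAULT_COHORT_SPEC = CohortSpec(
    groups={
        "HCC": GroupSpec(mu=1.37, k=1.1377, hazard=0.0089, hazard_ratio_pos=3.36,
                         log10_afp=(1.6, 1.0)),
        "ICC": GroupSpec(mu=1.42, k=1.4964),
        "BC": GroupSpec(mu=2.52, k=0.6271),
        "CRC": GroupSpec(mu=1.62, k=0.9780),
        "LCA": GroupSpec(mu=2.73, k=0.6827),
        "CHB/LC": GroupSpec(mu=0.10, k=0.0875, log10_afp=(0.8, 0.5)),
        "BHL": GroupSpec(mu=0.03, k=0.0767, log10_afp=(0.6, 0.4)),
        "HD": GroupSpec(mu=0.008, k=1000.0, log10_afp=(0.5, 0.3)),
    }
)


def zinb_positive_prob(pi: float, mu: float, k: float) -> float:
    """Closed-form P(count >= 1) under the zero-inflated NB model."""
    if mu == 0:
        return 0.0
    return float(1.0 - (pi + (1.0 - pi) * (k / (k + mu)) ** k))


def simulate_cohort(
    spec: CohortSpec | None = None,
    n_per_group: int | Mapping[str, int] = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a per-subject cohort table.

    Returns a DataFrame with columns ``subject_id``, ``group``,
    ``ctc_count`` and, for groups with an outcome model, ``recurrence``
    (event indicator) and ``ttr_months`` (time to recurrence or censoring).
    """
    if spec is None:
        spec = DEFAULT_COHORT_SPEC
    rng = np.random.default_rng(seed)
    rows = []
    for group, g in spec.groups.items():
        n = n_per_group[group] if isinstance(n_per_group, Mapping) else n_per_group
        if n < 1:
            raise ValueError(f"n_per_group must be >= 1 (group {group!r})")
        counts = rng.negative_binomial(g.k, g.k / (g.k + g.mu), size=n) \
            if g.mu > 0 else np.zeros(n, dtype=int)
        if g.pi > 0:
            counts = np.where(rng.random(n) < g.pi, 0, counts)
        for i, c in enumerate(counts):
            row: dict[str, object] = {
                "subject_id": f"{group.replace('/', '')}-{i:04d}",
                "group": group,
                "ctc_count": int(c),
            }
            if g.hazard is not None:
                h = g.hazard * (g.hazard_ratio_pos if c >= 1 else 1.0)
                event_time = rng.exponential(1.0 / h)
                censor_time = rng.uniform(*spec.censor_window)
                row["recurrence"] = int(event_time <= censor_time)
                row["ttr_months"] = float(min(event_time, censor_time))
            if g.log10_afp is not None:
                row["afp_ng_ml"] = float(10.0 ** rng.normal(*g.log10_afp))
            rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Spike-in experiments
# --------------------------------------------------------------------------


def spike_in_experiment(
    n_spiked: int,
    recovery_prob: float = 0.756,
    replicates: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Recovered counts per replicate when each spiked cell is recovered
    independently with probability ``recovery_prob``."""
    if not 0.0 <= recovery_prob <= 1.0:
        raise ValueError("recovery_prob must be in [0, 1]")
    if n_spiked < 0:
        raise ValueError("n_spiked must be >= 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.binomial(n_spiked, recovery_prob, size=replicates)


# --------------------------------------------------------------------------
# Genomic bin counts
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GroundTruthCN:
    """Ground-truth copy-number profile: per-chromosome segments (0-based
    half-open, tiling each chromosome without overlap) with integer CN."""

    segments: pd.DataFrame  # columns: chrom, start, end, cn
    ploidy: int = 2

    def __post_init__(self) -> None:
        seg = self.segments
        required = {"chrom", "start", "end", "cn"}
        if not required.issubset(seg.columns):
            raise ValueError(f"segments need columns {sorted(required)}")
        if (seg["cn"] < 0).any():
            raise ValueError("copy numbers must be >= 0")
        if (seg["cn"] != seg["cn"].astype(int)).any():
            raise ValueError("copy numbers must be integers")
        for chrom, sub in seg.groupby("chrom", sort=False):
            s = sub.sort_values("start")
            if (s["end"] <= s["start"]).any():
                raise ValueError(f"empty segment on {chrom}")
            if (s["start"].values[1:] != s["end"].values[:-1]).any():
                raise ValueError(f"segments do not tile {chrom} without gaps")

    def cn_at(self, bins: pd.DataFrame) -> np.ndarray:
        """Integer CN at each bin midpoint."""
        out = np.empty(len(bins), dtype=int)
        mid = (bins["start"].to_numpy() + bins["end"].to_numpy()) // 2
        for chrom, sub in self.segments.groupby("chrom", sort=False):
            sel = (bins["chrom"] == chrom).to_numpy()
            if not sel.any():
                continue
            s = sub.sort_values("start")
            idx = np.searchsorted(s["end"].to_numpy(), mid[sel], side="right")
            idx = np.clip(idx, 0, len(s) - 1)
            out[sel] = s["cn"].to_numpy()[idx]
        return out


#: Toy 3-chromosome genome used throughout the tests and examples.
TOY_CHROM_SIZES = {"chr1": 60_000_000, "chr2": 45_000_000, "chr3": 30_000_000}


def toy_genome_bins(bin_size: int = 500_000, seed: int = 0,
                    chrom_sizes: Mapping[str, int] | None = None) -> pd.DataFrame:
    """Fixed-width bins over the toy genome with reproducible GC content
    (Beta-distributed around 0.42, the genome-wide typical value)."""
    if chrom_sizes is None:
        chrom_sizes = TOY_CHROM_SIZES
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, size in chrom_sizes.items():
        for start in range(0, size, bin_size):
            rows.append((chrom, start, min(start + bin_size, size)))
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    bins["gc"] = np.clip(rng.beta(20, 27, size=len(bins)), 0.2, 0.8)
    return bins


def default_cn_truth(ploidy: int = 2) -> GroundTruthCN:
    """A hepatoma-like aneuploid truth on the toy genome: a two-copy gain
    and two single-copy losses, elsewhere diploid.  Gains and losses
    balance so the genome-wide mean CN equals the ploidy, matching the
    mean-normalization assumption of the default caller."""
    seg = pd.DataFrame(
        [
            ("chr1", 0, 20_000_000, 2),
            ("chr1", 20_000_000, 35_000_000, 4),
            ("chr1", 35_000_000, 60_000_000, 2),
            ("chr2", 0, 15_000_000, 1),
            ("chr2", 15_000_000, 45_000_000, 2),
            ("chr3", 0, 15_000_000, 1),
            ("chr3", 15_000_000, 30_000_000, 2),
        ],
        columns=["chrom", "start", "end", "cn"],
    )
    return GroundTruthCN(segments=seg, ploidy=ploidy)


def _check_bins_sorted(bins: pd.DataFrame) -> None:
    for chrom, sub in bins.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if (np.diff(starts) <= 0).any():
            raise ValueError(f"bins not sorted on {chrom}")
        if (starts[1:] < ends[:-1]).any():
            raise ValueError(f"bins overlap on {chrom}")


def simulate_bin_counts(
    truth: GroundTruthCN,
    bins: pd.DataFrame,
    mean_depth: float = 100.0,
    dispersion: float | None = 10.0,
    gc_bias_coeffs: tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-bin read counts from a ground-truth CN profile.

    Each bin's count is negative binomial with mean
    ``mean_depth · CN/ploidy · g(gc)`` where ``g`` is a quadratic GC
    response (coefficients ``(linear, quadratic)`` in centered GC)
    normalized to mean 1 over the bins, and ``dispersion`` is the NB size
    parameter (``None`` = Poisson).  Bins on CN-0 segments get exactly 0.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    _check_bins_sorted(bins)
    rng = np.random.default_rng(seed)
    cn = truth.cn_at(bins)
    gc = bins["gc"].to_numpy(dtype=float)
    c1, c2 = gc_bias_coeffs
    gdev = gc - gc.mean()
    g = 1.0 + c1 * gdev + c2 * gdev**2
    g = np.clip(g, 0.05, None)
    g = g / g.mean()
    mean = mean_depth * (cn / truth.ploidy) * g
    if dispersion is None or not np.isfinite(dispersion):
        counts = rng.poisson(mean)
    else:
        p = dispersion / (dispersion + mean)
        counts = rng.negative_binomial(dispersion, p)
    counts = np.where(cn == 0, 0, counts)
    out = bins[["chrom", "start", "end", "gc"]].copy()
    out["count"] = counts.astype(int)
    return out
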