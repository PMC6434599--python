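"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the statistical structure of a two-group ectocervical
study (DMPA users as cases vs women not using hormonal contraception as
controls): double-stained tissue images with a known positive-area layout,
multiplex cytokine plates with detection-limit censoring, per-event flow
tables with a nested gating structure, and a subject table whose confounders
(duration of sex work, vaginal douching) are correlated with group.

Tissue images are deliberately simple: cells are uniform-intensity disks with
a slight Gaussian edge blur over a flat autofluorescent background plus
Gaussian noise.  That forfeits realism (no texture, no spectral bleed, no
illumination gradients) but buys an unambiguous ground truth: the true
positive-area masks are computed by exact pixel counting on the noise-free
disks, so the image-quantification stage has a parameter-recovery oracle.

Everything is deterministic given the seed; each call owns a single
``numpy.random.Generator`` and touches no global state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .flowsum import FlowEvents, PANEL_COLUMNS
from .imquant import ImageBundle, RegionSet, rasterize_regions

__all__ = [
    "TissueSimParams",
    "GroundTruth",
    "CohortSimParams",
    "make_tissue_image",
    "make_cytokine_table",
    "make_flow_events",
    "make_subject_table",
    "write_simulation",
]

CELL_AMPLITUDE = 1000.0  # stain intensity of a positive cell above background
MUCUS_AMPLITUDE = 1500.0  # apical autofluorescent band, marker-B channel
ARTIFACT_AMPLITUDE = 3000.0
EDGE_BLUR_SIGMA = 0.8  # px; optical softening of disk edges


@dataclass
class TissueSimParams:
    """Layout and noise parameters for one synthetic double-stained section.

    Defaults describe the study conditions: a 0.5 um/px scan of a 512 px
    square field, epithelium occupying 60% of the frame, and a cell density
    giving a marker-A (CD4) positive area near 3% of the analyzed tissue —
    the scale of the real measurement.  ``frac_b_pos_given_a`` is the
    generative double-positive fraction that the headline percent-of-A
    statistic estimates.
    """

    height_px: int = 512
    width_px: int = 512
    pixel_size_um: float = 0.5
    epithelium_fraction: float = 0.6
    cell_density: float = 4000.0  # cells per mm^2 of epithelium
    frac_a_pos: float = 0.5
    frac_b_pos_given_a: float = 0.25
    frac_b_pos_given_nota: float = 0.10
    cell_radius_px: int = 4
    mucus_band: bool = True
    background_level: float = 100.0
    noise_sd: float = 8.0
    artifact_count: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height_px < 64 or self.width_px < 64:
            raise ValueError("image dimensions must be >= 64 px")
        for name in ("frac_a_pos", "frac_b_pos_given_a", "frac_b_pos_given_nota"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if not (0.0 < self.epithelium_fraction < 1.0):
            raise ValueError("epithelium_fraction must be in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.cell_radius_px < 1:
            raise ValueError("cell_radius_px must be >= 1")
        if not (self.pixel_size_um > 0 and self.cell_density >= 0):
            raise ValueError("pixel_size_um must be > 0 and cell_density >= 0")
        if self.artifact_count < 0:
            raise ValueError("artifact_count must be >= 0")


@dataclass
class GroundTruth:
    """Noise-free truth for one synthetic image (the test oracle).

    true_fracs holds the four area percentages (pct_a_total, pct_b_total,
    pct_ab_total, pct_ab_of_a) computed by exact pixel counting of the
    placed-disk masks inside the analysis region.
    """

    mask_a: np.ndarray
    mask_b: np.ndarray
    roi_polygons: list[np.ndarray]
    exclusion_polygons: list[np.ndarray]
    true_fracs: dict[str, float]


def _paint_disks(shape: tuple[int, int], centers: np.ndarray, radius: float) -> np.ndarray:
    """Exact disk union: pixel in mask iff its center is within radius of a cell center."""
    mask = np.zeros(shape, dtype=bool)
    if len(centers) == 0:
        return mask
    h, w = shape
    r_int = int(np.ceil(radius)) + 1
    for cx, cy in centers:
        j0, j1 = max(0, int(cx) - r_int), min(w, int(cx) + r_int + 1)
        i0, i1 = max(0, int(cy) - r_int), min(h, int(cy) + r_int + 1)
        jj, ii = np.meshgrid(np.arange(j0, j1), np.arange(i0, i1))
        d2 = (jj + 0.5 - cx) ** 2 + (ii + 0.5 - cy) ** 2
        mask[i0:i1, j0:j1] |= d2 <= radius**2
    return mask


def make_tissue_image(params: TissueSimParams) -> tuple[ImageBundle, GroundTruth]:
    """Synthesize one double-stained section plus its ground truth.

    The epithelium ROI is a full-width band occupying ``epithelium_fraction``
    of the frame height (bottom of the frame); when ``mucus_band`` is set, a
    high-intensity marker-B band sits apically just *outside* the ROI,
    mimicking autofluorescent mucus that the exclusion conventions must keep
    out of the measurement.  Optional artifacts are bright blobs inside the
    ROI, each wrapped in an exclusion polygon.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    h, w = p.height_px, p.width_px
    y0 = float(round(h * (1.0 - p.epithelium_fraction)))
    roi = np.array([[0.0, y0], [w, y0], [float(w), float(h)], [0.0, float(h)]])

    # artifacts: bright squares inside the ROI, each with an exclusion polygon
    exclusions: list[np.ndarray] = []
    artifact_boxes: list[tuple[int, int, int]] = []
    a_side = max(6, p.cell_radius_px * 4)
    for _ in range(p.artifact_count):
        ax = rng.uniform(a_side, w - a_side)
        ay = rng.uniform(y0 + a_side, h - a_side)
        x0, y0a = int(ax - a_side / 2), int(ay - a_side / 2)
        artifact_boxes.append((x0, y0a, a_side))
        m = 2.0  # exclusion margin, px
        exclusions.append(
            np.array(
                [
                    [x0 - m, y0a - m],
                    [x0 + a_side + m, y0a - m],
                    [x0 + a_side + m, y0a + a_side + m],
                    [x0 - m, y0a + a_side + m],
                ]
            )
        )

    regions = RegionSet(roi_polygons=[roi], exclusion_polygons=exclusions)
    analysis = rasterize_regions(regions, (h, w), p.pixel_size_um)

    # cell placement: Poisson count over the epithelium band area
    roi_area_mm2 = (w * (h - y0)) * (p.pixel_size_um * 1e-3) ** 2
    n_cells = int(rng.poisson(p.cell_density * roi_area_mm2))
    r = p.cell_radius_px
    if n_cells > 0:
        cx = rng.uniform(r, w - r, size=n_cells)
        cy = rng.uniform(y0 + r, h - r, size=n_cells)
        centers = np.column_stack([cx, cy])
        is_a = rng.random(n_cells) < p.frac_a_pos
        p_b = np.where(is_a, p.frac_b_pos_given_a, p.frac_b_pos_given_nota)
        is_b = rng.random(n_cells) < p_b
    else:
        centers = np.empty((0, 2))
        is_a = is_b = np.zeros(0, dtype=bool)

    shape = (h, w)
    disks_all = _paint_disks(shape, centers, r)
    disks_a = _paint_disks(shape, centers[is_a], r)
    disks_b = _paint_disks(shape, centers[is_b], r)

    def _channel(fg: np.ndarray, extra: np.ndarray | None = None) -> np.ndarray:
        img = np.full(shape, p.background_level, dtype=float)
        img += CELL_AMPLITUDE * gaussian_filter(fg.astype(float), EDGE_BLUR_SIGMA)
        if extra is not None:
            img += extra
        if p.noise_sd > 0:
            img += rng.normal(0.0, p.noise_sd, size=shape)
        return np.clip(img, 0.0, None)

    mucus = np.zeros(shape)
    if p.mucus_band and y0 >= 1:
        band_h = min(int(y0), max(6, h // 32))
        mucus[int(y0) - band_h : int(y0), :] = MUCUS_AMPLITUDE
    artifacts = np.zeros(shape)
    for x0, y0a, side in artifact_boxes:
        artifacts[y0a : y0a + side, x0 : x0 + side] = ARTIFACT_AMPLITUDE

    bundle = ImageBundle(
        channels={
            "nuclei": _channel(disks_all),
            "markerA": _channel(disks_a, artifacts),
            "markerB": _channel(disks_b, mucus + artifacts),
        },
        pixel_size_um=p.pixel_size_um,
        image_id=f"sim-{p.seed}",
    )

    mask_a = disks_a & analysis
    mask_b = disks_b & analysis
    n_m = int(analysis.sum())
    n_a = int(mask_a.sum())
    n_b = int(mask_b.sum())
    n_ab = int((mask_a & mask_b).sum())
    truth = GroundTruth(
        mask_a=mask_a,
        mask_b=mask_b,
        roi_polygons=[roi],
        exclusion_polygons=exclusions,
        true_fracs={
            "pct_a_total": 100.0 * n_a / n_m,
            "pct_b_total": 100.0 * n_b / n_m,
            "pct_ab_total": 100.0 * n_ab / n_m,
            "pct_ab_of_a": (100.0 * n_ab / n_a) if n_a else float("nan"),
        },
    )
    return bundle, truth


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------


@dataclass
class CohortSimParams:
    """Two-group cohort structure with confounding, mirroring the study design.

    effects: per-endpoint case-vs-control shift — a location shift on the
    log10 scale for analytes, an additive shift for proportions.
    censor_rates: per-group mapping analyte -> probability that a raw value
    falls below the assay's lower detection limit.
    Confounders: cases douche more often and have a shorter duration of sex
    work, as in the source cohort (douching 46.7% vs 9.5%; duration medians
    21 vs 30 months).
    """

    n_case: int = 15
    n_control: int = 20
    effects: dict[str, float] = field(default_factory=dict)
    censor_rates: dict[str, dict[str, float]] = field(default_factory=dict)
    douching_p: tuple[float, float] = (0.467, 0.095)  # (case, control)
    duration_median_months: tuple[float, float] = (21.0, 30.0)
    duration_log_sd: tuple[float, float] = (0.45, 0.30)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 0 or self.n_control < 0:
            raise ValueError("group sizes must be >= 0")
        if self.n_case + self.n_control < 2:
            raise ValueError("need at least 2 subjects overall")
        for p in self.douching_p:
            if not (0.0 <= p <= 1.0):
                raise ValueError("douching probabilities must be in [0, 1]")
        for grp in self.censor_rates.values():
            for v in grp.values():
                if not (0.0 <= v <= 1.0):
                    raise ValueError("censor rates must be in [0, 1]")


GROUP_CASE = "DMPA"
GROUP_CONTROL = "no_HC"


def make_subject_table(params: CohortSimParams) -> pd.DataFrame:
    """Subject covariates: group, douching, duration of sex work, cycle data.

    Controls carry day-since-menses and a paired progesterone measurement
    (study visit and a visit two weeks earlier) generated so the
    luteal:follicular ratio has median ~6.2; cases (injectable progestin
    users) have no cycle, so those fields are missing.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    rows = []
    for grp, n, douche_p, dur_med, dur_sd in (
        (GROUP_CASE, p.n_case, p.douching_p[0], p.duration_median_months[0], p.duration_log_sd[0]),
        (GROUP_CONTROL, p.n_control, p.douching_p[1], p.duration_median_months[1], p.duration_log_sd[1]),
    ):
        for i in range(n):
            douching = bool(rng.random() < douche_p)
            duration = float(np.exp(rng.normal(np.log(dur_med), dur_sd)))
            if grp == GROUP_CONTROL:
                menses_day = int(np.clip(round(rng.normal(21.0, 2.0)), 16, 28))
                prog_prior = float(np.exp(rng.normal(0.0, 0.4)))  # follicular
                ratio = float(np.exp(rng.normal(np.log(6.2), 0.5)))
                prog_study = prog_prior * ratio
            else:
                menses_day = pd.NA
                prog_prior = prog_study = float("nan")
            rows.append(
                {
                    "subject_id": f"{grp}-{i:03d}",
                    "group": grp,
                    "douching": int(douching),
                    "duration_sex_work": duration,
                    "menses_day": menses_day,
                    "progesterone_prior_visit": prog_prior,
                    "progesterone_study_visit": prog_study,
                }
            )
    return pd.DataFrame(rows)


def make_cytokine_table(
    params: CohortSimParams,
    analytes: Sequence[str],
    limits: Mapping[str, tuple[float, float]],
    base_log10: Mapping[str, float] | None = None,
    log10_sd: float = 0.5,
    replicate_log10_sd: float = 0.03,
    over_uld_rates: Mapping[str, Mapping[str, float]] | None = None,
    subjects: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Duplicate-well multiplex measurements with group shifts and censoring.

    Each sample x analyte has a latent log-normal concentration
    (log10 ~ Normal(mu + shift*case, log10_sd)); with the configured per-group
    probability the latent value is replaced by one below the lower limit
    (uniform on (0.1, 0.9) x LLD) or above the upper limit.  Two replicate
    wells are drawn around the latent value with small multiplicative noise.

    Columns: sample_id, group, analyte, rep1, rep2, lld, uld.
    """
    if not analytes:
        raise ValueError("analytes must be non-empty")
    for a in analytes:
        lld, uld = limits[a]
        if lld >= uld:
            raise ValueError(f"analyte {a!r}: LLD ({lld}) must be < ULD ({uld})")
    p = params
    rng = np.random.default_rng(p.seed + 1)
    if subjects is None:
        subjects = make_subject_table(params)
    base_log10 = base_log10 or {}
    over_uld_rates = over_uld_rates or {}
    rows = []
    for _, subj in subjects.iterrows():
        is_case = subj["group"] == GROUP_CASE
        grp_key = "case" if is_case else "control"
        for a in analytes:
            lld, uld = limits[a]
            mu = base_log10.get(a, np.log10(lld) + 1.0)
            shift = p.effects.get(a, 0.0) if is_case else 0.0
            latent = 10.0 ** rng.normal(mu + shift, log10_sd)
            u = rng.random()
            low_p = p.censor_rates.get(grp_key, {}).get(a, 0.0)
            high_p = over_uld_rates.get(grp_key, {}).get(a, 0.0)
            if u < low_p:
                latent = lld * rng.uniform(0.1, 0.9)
            elif u < low_p + high_p:
                latent = uld * rng.uniform(1.05, 1.5)
            reps = latent * 10.0 ** rng.normal(0.0, replicate_log10_sd, size=2)
            rows.append(
                {
                    "sample_id": subj["subject_id"],
                    "group": subj["group"],
                    "analyte": a,
                    "rep1": float(reps[0]),
                    "rep2": float(reps[1]),
                    "lld": float(lld),
                    "uld": float(uld),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# flow events
# ---------------------------------------------------------------------------

#: conditional pass fractions for the default hierarchy
DEFAULT_SUBSET_SPEC = {
    "singlet": 0.95,
    "lymphocyte": 0.85,
    "live": 0.90,
    "cd3": 0.50,
    "cd4": 0.70,
}

#: log-normal medians for marker intensities on CD4+ events
DEFAULT_MFI_SPEC = {"CCR5": 300.0, "CD69": 2500.0, "CD95": 3000.0, "HLA-DR": 500.0,
                    "CD161": 200.0}

_GATE_ORDER = ("singlet", "lymphocyte", "live", "cd3", "cd4")


def make_flow_events(
    n_events: int,
    subset_spec: Mapping[str, float] | None = None,
    mfi_spec: Mapping[str, float] | None = None,
    seed: int = 0,
    sample_id: str = "",
    compartment: str = "blood",
    marker_log10_sd: float = 0.15,
) -> FlowEvents:
    """Draw events whose expected per-gate pass fractions equal subset_spec.

    subset_spec gives each gate's pass probability *conditional on its
    parent*, for the hierarchy singlet -> lymphocyte -> live -> cd3 -> cd4;
    membership indicators are drawn independently per gate, so an event is in
    a gate iff every indicator up to that gate fired.  Channel intensities
    are then laid out so the default gate tree recovers the memberships:
    passing events land inside the gate region, failing events far outside.
    Marker intensities on CD4+ events are log-normal around ``mfi_spec``
    medians (an MFI ground truth).
    """
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    spec = dict(DEFAULT_SUBSET_SPEC)
    spec.update(subset_spec or {})
    for k, v in spec.items():
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"subset_spec[{k!r}] must be in [0, 1] (got {v})")
    unknown = set(spec) - set(_GATE_ORDER)
    if unknown:
        raise ValueError(f"unknown gates in subset_spec: {sorted(unknown)}")
    mfis = dict(DEFAULT_MFI_SPEC)
    mfis.update(mfi_spec or {})

    rng = np.random.default_rng(seed)
    n = int(n_events)
    member = {}
    alive = np.ones(n, dtype=bool)
    for g in _GATE_ORDER:
        alive = alive & (rng.random(n) < spec[g])
        member[g] = alive.copy()

    fsc_a = rng.normal(50000, 8000, n).clip(16000, 94000)
    ratio = np.where(member["singlet"], rng.normal(1.0, 0.02, n), 0.55)
    fsc_h = fsc_a * ratio
    ssc_a = np.where(member["lymphocyte"],
                     rng.normal(20000, 5000, n).clip(2000, 49000),
                     rng.normal(120000, 10000, n).clip(60000, None))
    viability = np.where(member["live"],
                         rng.normal(200, 80, n).clip(0, 900),
                         rng.normal(3000, 300, n).clip(1200, None))

    def _marker(name: str, pos: np.ndarray, pos_median: float, neg_median: float) -> np.ndarray:
        vals = 10.0 ** rng.normal(np.log10(neg_median), marker_log10_sd, n)
        vals[pos] = 10.0 ** rng.normal(np.log10(pos_median), marker_log10_sd, pos.sum())
        return vals

    cd3 = _marker("CD3", member["cd3"], 1500.0, 50.0)
    cd4 = _marker("CD4", member["cd4"], 1200.0, 40.0)
    data = {
        "FSC-A": fsc_a,
        "FSC-H": fsc_h,
        "SSC-A": ssc_a,
        "viability": viability,
        "CD3": cd3,
        "CD4": cd4,
    }
    for m in ("CCR5", "CD69", "CD95", "HLA-DR", "CD161"):
        data[m] = _marker(m, member["cd4"], mfis[m], 30.0)
    df = pd.DataFrame(data, columns=list(PANEL_COLUMNS))
    return FlowEvents(data=df, sample_id=sample_id, compartment=compartment)


# ---------------------------------------------------------------------------
# on-disk simulation bundle
# ---------------------------------------------------------------------------


def write_simulation(
    out_dir: str | Path,
    cohort: CohortSimParams,
    tissue: TissueSimParams | None = None,
    analytes: Sequence[str] = ("IL-1b", "MIP-1a", "MIP-3a", "IL-10"),
    limits: Mapping[str, tuple[float, float]] | None = None,
    n_flow_events: int = 20000,
    group_frac_b_given_a: tuple[float, float] = (0.26, 0.16),
) -> dict:
    """Materialize a full synthetic study on disk; returns the manifest dict.

    One tissue image per subject (cases and controls differ in the generative
    double-positive-of-A fraction, default 26% vs 16%), one cytokine plate,
    one flow-event table per subject, and the subject covariate table.
    Layout: TIFF + GeoJSON per image, TSVs for tables, manifest.json on top.
    """
    from .imquant import write_image_bundle, write_regions  # local: avoid cycle at import

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tissue = tissue or TissueSimParams()
    limits = limits or {a: (3.2, 10000.0) for a in analytes}
    rng = np.random.default_rng(cohort.seed + 7)

    subjects = make_subject_table(cohort)
    subjects.to_csv(out / "subjects.tsv", sep="\t", index=False)

    files: list[str] = ["subjects.tsv"]
    image_rows = []
    for k, (_, subj) in enumerate(subjects.iterrows()):
        is_case = subj["group"] == GROUP_CASE
        tp = TissueSimParams(
            **{
                **asdict(tissue),
                "frac_b_pos_given_a": group_frac_b_given_a[0 if is_case else 1],
                "seed": int(rng.integers(0, 2**31 - 1)),
            }
        )
        bundle, truth = make_tissue_image(tp)
        bundle.image_id = subj["subject_id"]
        stem = f"image_{subj['subject_id']}"
        write_image_bundle(bundle, out / f"{stem}.tif")
        write_regions(
            RegionSet(truth.roi_polygons, truth.exclusion_polygons),
            out / f"{stem}.geojson",
        )
        files += [f"{stem}.tif", f"{stem}.geojson"]
        image_rows.append(
            {"subject_id": subj["subject_id"], "group": subj["group"],
             "image": f"{stem}.tif", "regions": f"{stem}.geojson",
             **{f"true_{k2}": v for k2, v in truth.true_fracs.items()}}
        )

        ev = make_flow_events(
            n_flow_events,
            subset_spec={"cd4": 0.70 if is_case else 0.69},
            mfi_spec={"CCR5": 207.0 if is_case else 322.0},
            seed=int(rng.integers(0, 2**31 - 1)),
            sample_id=subj["subject_id"],
            compartment="blood",
        )
        ev.data.to_csv(out / f"flow_{subj['subject_id']}.tsv", sep="\t", index=False)
        files.append(f"flow_{subj['subject_id']}.tsv")

    pd.DataFrame(image_rows).to_csv(out / "images.tsv", sep="\t", index=False)
    files.append("images.tsv")

    cyto = make_cytokine_table(cohort, analytes, limits, subjects=subjects)
    cyto.to_csv(out / "cytokines.tsv", sep="\t", index=False)
    files.append("cytokines.tsv")
    lim_df = pd.DataFrame(
        [{"analyte": a, "lld": l, "uld": u} for a, (l, u) in limits.items()]
    )
    lim_df.to_csv(out / "limits.tsv", sep="\t", index=False)
    files.append("limits.tsv")

    manifest = {
        "seed": cohort.seed,
        "cohort_params": asdict(cohort),
        "tissue_params": asdict(tissue),
        "group_frac_b_given_a": list(group_frac_b_given_a),
        "n_flow_events": n_flow_events,
        "files": sorted(files),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
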