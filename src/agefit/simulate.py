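"""Synthetic cohorts and regional volumes with known ground truth.

The generator emulates the statistical structure the analysis assumes, so
every pipeline stage can be exercised and validated without any MRI data:

* a cohort of older adults (ages 55-87, mean ~69.5, SD ~8.5, near-balanced
  gender) whose BMI, diastolic pressure, pulse pressure and activity decline
  or rise with age through a Gaussian copula with configurable correlation
  targets (defaults: age-BMI -0.48, age-diastolic -0.39, age-pulse-pressure
  +0.36);
* per-region bilateral volumes built additively from an age slope, a
  continuous-fitness (eCRF) slope, shared latent factors in block structure,
  an eTIV head-size component, and Gaussian noise; ventricle age slopes are
  positive (ventricles expand with age), tissue slopes negative;
* a planted *overlap* between the age and fitness effect profiles: the
  correlation across regions between the age-decline profile (-beta_age)
  and the fitness-benefit profile (+beta_fit) is resampled until it is
  within ±0.02 of the requested ``profile_overlap_rho``, so the pipeline's
  estimated d-profile correlation has a known target.

Region means are plausible per-class magnitudes only; all downstream
statistics are invariant to them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import ROIAtlas, load_atlas
from .cohort import add_fitness
from .config import ECRFModel, load_ecrf_model

_MU_BY_GROUP = {
    "Frontal": 12000.0, "Temporal": 11000.0, "Parietal": 12000.0,
    "Occipital": 9000.0, "Insula": 8000.0, "Cingulate": 8000.0,
    "Corpus Callosum": 6000.0, "Subcortical": 8000.0, "Ventricle": 12000.0,
}


@dataclass
class SyntheticSpec:
    """All knobs of the generator; the defaults are the study conditions."""

    n: int = 54
    seed: int = 0
    age_mean: float = 69.5
    age_sd: float = 8.5
    age_range: tuple[float, float] = (55.0, 87.0)
    female_fraction: float = 29 / 54
    # marginal means/SDs of the copula-coupled physiology
    bmi_mean: float = 27.46
    bmi_sd: float = 5.27
    hr_mean: float = 72.90
    hr_sd: float = 10.62
    diastolic_mean: float = 79.28
    diastolic_sd: float = 8.16
    pulse_pressure_mean: float = 57.63
    pulse_pressure_sd: float = 14.01
    # correlation targets with age
    r_age_bmi: float = -0.48
    r_age_diastolic: float = -0.39
    r_age_pulse_pressure: float = 0.36
    r_age_activity: float = -0.30
    n_screen_fail: int = 0
    # volume model
    profile_overlap_rho: float = 0.08
    n_factors: int = 5
    beta_age_scale: float = 40.0      # mm^3/year, magnitude of age slopes
    beta_age_spread: float = 12.0
    ventricle_age_gain: float = 2.0   # ventricle slopes this much larger
    beta_fit_loc: float = 40.0        # mm^3 per MET
    beta_fit_scale: float = 60.0
    factor_loading: float = 250.0     # mm^3 per latent-factor SD
    noise_sd: float = 300.0           # mm^3 residual SD (constant-noise mode)
    sd_total: float | None = 900.0    # mm^3; equalize per-region total SD
    hemi_asym_sd: float = 25.0        # mm^3 left/right asymmetry
    etiv_female: tuple[float, float] = (1.45e6, 1.2e5)
    etiv_male: tuple[float, float] = (1.60e6, 1.3e5)
    # proportional-scaling gain: gamma_etiv = coupling * mu / nominal mean
    # eTIV, so 1.0 means regions scale one-for-one with head size
    etiv_coupling: float = 1.0

    def nominal_etiv_mean(self) -> float:
        f = self.female_fraction
        return f * self.etiv_female[0] + (1 - f) * self.etiv_male[0]
    on_negative: str = "resample"     # or "error"
    n_reference: int = 8
    ecrf_model: ECRFModel | None = None

    def model(self) -> ECRFModel:
        return self.ecrf_model or load_ecrf_model()


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests."""

    beta_age: pd.Series = field(repr=False)     # total (marginal) age gradient
    beta_fit: pd.Series = field(repr=False)
    overlap_corr: float = 0.0           # corr(-beta_age, beta_fit), realized
    factor_block: pd.Series = field(default=None, repr=False)
    mu: pd.Series = field(default=None, repr=False)
    # raw slope vectors actually entering the volume mean structure
    beta_age_direct: pd.Series = field(default=None, repr=False)
    beta_fit_direct: pd.Series = field(default=None, repr=False)


def _rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(spec.seed), stream]))


def _copula_matrix(spec: SyntheticSpec) -> np.ndarray:
    """Latent correlation matrix over (age, bmi, dia, pp, hr, activity)."""
    r = np.eye(6)
    targets = [spec.r_age_bmi, spec.r_age_diastolic, spec.r_age_pulse_pressure,
               0.0, spec.r_age_activity]
    # the age margin is a truncated normal, which attenuates Pearson
    # correlations relative to the latent Gaussian by corr(g(z), z), where
    # g maps the latent normal through the copula to the truncated margin;
    # inflate the latent correlations to compensate (Gauss quadrature)
    a, b = (np.array(spec.age_range) - spec.age_mean) / spec.age_sd
    z = np.linspace(-8, 8, 4001)
    w = stats.norm.pdf(z)
    w /= w.sum()
    g = stats.truncnorm.ppf(stats.norm.cdf(z), a, b)
    g = (g - (w * g).sum()) / np.sqrt((w * g**2).sum() - (w * g).sum() ** 2)
    atten = float((w * g * z).sum())
    for j, t in enumerate(targets, start=1):
        r[0, j] = r[j, 0] = np.clip(t / atten, -0.99, 0.99)
    eig = np.linalg.eigvalsh(r)
    if eig.min() <= 0:
        raise ValueError("infeasible correlation targets: matrix not PSD")
    return r


def generate_cohort(spec: SyntheticSpec) -> pd.DataFrame:
    """Sample a cohort table with the configured demographic structure.

    The returned table carries the raw input columns plus the derived
    fitness columns (bmi, pulse_pressure, activity_category, ecrf, vo2max).
    """
    rng = _rng(spec, 0)
    n = spec.n
    z = rng.multivariate_normal(np.zeros(6), _copula_matrix(spec), size=n)
    u = stats.norm.cdf(z)
    a, b = (np.array(spec.age_range) - spec.age_mean) / spec.age_sd
    age = stats.truncnorm.ppf(u[:, 0], a, b, loc=spec.age_mean, scale=spec.age_sd)
    bmi = stats.norm.ppf(u[:, 1], spec.bmi_mean, spec.bmi_sd)
    dia = stats.norm.ppf(u[:, 2], spec.diastolic_mean, spec.diastolic_sd)
    pp = np.clip(
        stats.norm.ppf(u[:, 3], spec.pulse_pressure_mean, spec.pulse_pressure_sd),
        5.0, None,
    )
    hr = stats.norm.ppf(u[:, 4], spec.hr_mean, spec.hr_sd)
    act = u[:, 5]
    n_f = int(round(spec.female_fraction * n))
    gender = np.array(["F"] * n_f + ["M"] * (n - n_f))
    rng.shuffle(gender)
    height = np.where(
        gender == "F", rng.normal(1.63, 0.06, n), rng.normal(1.76, 0.07, n)
    )
    weight = bmi * height**2
    aerobic = np.where(act < 0.3, 0.0, np.round(240 * (act - 0.3) / 0.7))
    low_ex = np.round(rng.uniform(0, 180, n))
    bdi = rng.integers(0, 11, n).astype(float)
    mmms = rng.integers(52, 58, n).astype(float)
    for i in range(min(spec.n_screen_fail, n)):
        if i % 2 == 0:
            bdi[i] = 20.0
        else:
            mmms[i] = 50.0
    cohort = pd.DataFrame(
        {
            "id": [f"sub-{i:04d}" for i in range(n)],
            "age": age, "gender": gender, "height": height, "weight": weight,
            "resting_hr": hr, "low_exertion_min": low_ex, "aerobic_min": aerobic,
            "bdi": bdi, "mmms": mmms, "systolic": dia + pp, "diastolic": dia,
        }
    )
    return add_fitness(cohort, spec.model())


def make_profile_pair(
    spec: SyntheticSpec, atlas: ROIAtlas | None = None, max_tries: int = 1000
) -> tuple[pd.Series, pd.Series, float]:
    """Per-region age and fitness slope vectors with planted overlap.

    Returns (beta_age, beta_fit, realized overlap correlation), where the
    overlap is corr(-beta_age, beta_fit) across regions: positive overlap
    means fitness benefits are largest where age-related decline is largest.
    Vectors are resampled until the realized overlap is within ±0.02 of
    ``spec.profile_overlap_rho``.
    """
    atlas = atlas or load_atlas()
    if len(atlas.regions) < 6:
        raise ValueError("need at least 6 regions")
    rho = spec.profile_overlap_rho
    if not -1.0 <= rho <= 1.0:
        raise ValueError("|profile_overlap_rho| must be <= 1")
    ventricle = atlas.table.set_index("region")["group"].eq("Ventricle")
    rng = _rng(spec, 1)
    for _ in range(max_tries):
        mag = np.abs(rng.normal(spec.beta_age_scale, spec.beta_age_spread,
                                len(atlas.regions)))
        mag = np.where(ventricle.to_numpy(), mag * spec.ventricle_age_gain, mag)
        beta_age = np.where(ventricle.to_numpy(), mag, -mag)
        decline = -beta_age
        if decline.std() == 0:  # degenerate all-zero-slope spec
            beta_fit = np.full_like(decline, spec.beta_fit_loc)
            return (
                pd.Series(beta_age, index=atlas.regions, name="beta_age"),
                pd.Series(beta_fit, index=atlas.regions, name="beta_fit"),
                float("nan"),
            )
        # enforce the overlap on the effect-profile region set: that subset
        # is what the d-profile correlation downstream is computed over
        sub = atlas.table["in_profile"].to_numpy(bool)
        dz_sub = (decline[sub] - decline[sub].mean()) / decline[sub].std()
        noise = rng.normal(size=int(sub.sum()))
        noise = noise - noise.mean()
        # remove the component along dz so the planted corr is exact in-sample
        noise = noise - (noise @ dz_sub) / (dz_sub @ dz_sub) * dz_sub
        noise = noise / noise.std()
        benefit = np.empty_like(decline)
        benefit[sub] = rho * dz_sub + np.sqrt(1 - rho**2) * noise
        dz_out = (decline[~sub] - decline[sub].mean()) / decline[sub].std()
        benefit[~sub] = rho * dz_out + np.sqrt(1 - rho**2) * rng.normal(
            size=int((~sub).sum())
        )
        beta_fit = spec.beta_fit_loc + spec.beta_fit_scale * benefit
        realized = float(np.corrcoef(decline[sub], beta_fit[sub])[0, 1])
        if abs(realized - rho) <= 0.02:
            return (
                pd.Series(beta_age, index=atlas.regions, name="beta_age"),
                pd.Series(beta_fit, index=atlas.regions, name="beta_fit"),
                realized,
            )
    raise RuntimeError("could not hit the requested profile overlap")


def _stratified_contrasts(cohort: pd.DataFrame):
    """Group-mean contrasts of (age, eCRF) under the stratified design.

    Returns (M, (delta_age_agesplit, delta_ecrf_fitsplit)) where M is the
    2x2 matrix of young-minus-old and high-minus-low mean differences in
    age and eCRF, or None when the design is degenerate.
    """
    from .stratify import stratify  # deferred: stratify imports cohort tools

    try:
        design = stratify(cohort)
    except ValueError:
        return None
    merged = cohort.merge(design, on="id")
    young = (merged["age_score"] <= 0).to_numpy()
    high = (merged["fitness_score"] == 1).to_numpy()
    if young.all() or not young.any() or high.all() or not high.any():
        return None
    d_age_a = merged["age"][young].mean() - merged["age"][~young].mean()
    d_fit_a = merged["ecrf"][young].mean() - merged["ecrf"][~young].mean()
    d_age_f = merged["age"][high].mean() - merged["age"][~high].mean()
    d_fit_f = merged["ecrf"][high].mean() - merged["ecrf"][~high].mean()
    m = np.array([[d_age_a, d_fit_a], [d_age_f, d_fit_f]])
    if abs(np.linalg.det(m)) < 1e-8:
        return None
    return m, (d_age_a, d_fit_f)


def _region_means(atlas: ROIAtlas) -> pd.Series:
    return pd.Series(
        [_MU_BY_GROUP[g] for g in atlas.table["group"]], index=atlas.regions
    )


def generate_volumes(
    cohort: pd.DataFrame,
    spec: SyntheticSpec,
    atlas: ROIAtlas | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Native (hemisphere-resolved) volume table for a generated cohort.

    Each bilateral-combined region volume is

        V = mu + beta_age (age - mean) + beta_fit (eCRF - mean)
            + loading * f_block + gamma_etiv (eTIV - mean) + noise,

    then split into left/right halves with small asymmetry noise for paired
    regions.  Requires the cohort's ``ecrf`` column (continuous fitness
    drives the volumes; dichotomization is an analysis choice downstream).
    """
    atlas = atlas or load_atlas()
    if "ecrf" not in cohort.columns:
        raise ValueError("cohort must carry an 'ecrf' column (run add_fitness)")
    rng = _rng(spec, 2)
    beta_age, beta_fit, realized = make_profile_pair(spec, atlas)
    regions = atlas.regions
    p = len(regions)
    n = len(cohort)
    mu = _region_means(atlas)
    block = pd.Series(np.arange(p) % spec.n_factors, index=regions, name="block")
    age_c = cohort["age"].to_numpy(float) - cohort["age"].mean()
    fit_c = cohort["ecrf"].to_numpy(float) - cohort["ecrf"].mean()
    # The planted profiles are *group-contrast* profiles: what the age-half
    # split and the stratified fitness split measure.  Age and eCRF are
    # entangled (eCRF declines with age, and the nested median split leaves
    # a small residual age difference between fitness groups), so the raw
    # slope vectors entering the mean structure are obtained by solving, per
    # region, the 2x2 system that maps (age slope, fitness slope) onto the
    # two group contrasts.  This makes the planted profiles identifiable by
    # the pipeline regardless of that entanglement.
    decline = -beta_age.to_numpy()
    benefit = beta_fit.to_numpy()
    contrasts = _stratified_contrasts(cohort)
    if contrasts is None:
        beta_age_direct, beta_fit_direct = -decline, benefit
    else:
        m, (d_age_a, d_fit_f) = contrasts
        rhs = np.column_stack([-decline * d_age_a, benefit * d_fit_f])
        solved = rhs @ np.linalg.inv(m).T
        beta_age_direct, beta_fit_direct = solved[:, 0], solved[:, 1]
    etiv_f = rng.normal(*spec.etiv_female, n)
    etiv_m = rng.normal(*spec.etiv_male, n)
    etiv = np.where(cohort["gender"].to_numpy() == "F", etiv_f, etiv_m)
    factors = rng.normal(size=(n, spec.n_factors))
    gamma = spec.etiv_coupling * mu.to_numpy() / spec.nominal_etiv_mean()
    base = (
        mu.to_numpy()[None, :]
        + np.outer(age_c, beta_age_direct)
        + np.outer(fit_c, beta_fit_direct)
        + spec.factor_loading * factors[:, block.to_numpy()]
        + np.outer(etiv - etiv.mean(), gamma)
    )
    if spec.sd_total is None:
        noise_sd = np.full(p, spec.noise_sd)
    else:
        # plant effects on a common standardized scale: per-region noise
        # absorbs the variance not taken by the structural components, so
        # the total (eTIV-free) SD is sd_total for every region it can be
        cov = np.cov(np.column_stack([age_c, fit_c]), rowvar=False)
        slopes = np.column_stack([beta_age_direct, beta_fit_direct])
        struct = np.einsum("ri,ij,rj->r", slopes, cov, slopes) + spec.factor_loading**2
        noise_sd = np.sqrt(np.clip(spec.sd_total**2 - struct, 100.0**2, None))
    noise = rng.normal(size=(n, p)) * noise_sd[None, :]
    vol = base + noise
    for _ in range(100):
        neg = vol <= 0
        if not neg.any():
            break
        if spec.on_negative == "error":
            raise ValueError("negative generated volume")
        sd_mat = np.broadcast_to(noise_sd[None, :], vol.shape)
        vol[neg] = base[neg] + rng.normal(size=int(neg.sum())) * sd_mat[neg]
    else:
        vol = np.clip(vol, 1.0, None)
    bilat = pd.DataFrame(vol, index=pd.Index(cohort["id"], name="id"), columns=regions)
    native = pd.DataFrame(index=bilat.index)
    for region in regions:
        if region in atlas.paired_regions:
            asym = rng.normal(0, spec.hemi_asym_sd, n)
            native[f"lh_{region}"] = bilat[region] / 2 + asym
            native[f"rh_{region}"] = bilat[region] / 2 - asym
        else:
            native[region] = bilat[region]
    native["etiv"] = etiv
    native["role"] = "analysis"
    truth = GroundTruth(
        beta_age=beta_age, beta_fit=beta_fit, overlap_corr=realized,
        factor_block=block, mu=mu,
        beta_age_direct=pd.Series(beta_age_direct, index=regions),
        beta_fit_direct=pd.Series(beta_fit_direct, index=regions),
    )
    return native, truth


def generate_reference_volumes(
    spec: SyntheticSpec,
    truth: GroundTruth,
    analysis_cohort: pd.DataFrame,
    atlas: ROIAtlas | None = None,
) -> pd.DataFrame:
    """Young-adult reference scans used only for head-size normalization."""
    atlas = atlas or load_atlas()
    rng = _rng(spec, 3)
    n = spec.n_reference
    age = rng.uniform(19, 22, n)
    gender = np.array(["F"] * (n - n // 2) + ["M"] * (n // 2))
    etiv = np.where(
        gender == "F", rng.normal(*spec.etiv_female, n), rng.normal(*spec.etiv_male, n)
    )
    ecrf = rng.normal(12.0, 2.0, n)
    age_c = age - analysis_cohort["age"].mean()
    fit_c = ecrf - analysis_cohort["ecrf"].mean()
    regions = atlas.regions
    gamma = spec.etiv_coupling * truth.mu.to_numpy() / spec.nominal_etiv_mean()
    beta_age = (
        truth.beta_age_direct if truth.beta_age_direct is not None else truth.beta_age
    )
    beta_fit = (
        truth.beta_fit_direct if truth.beta_fit_direct is not None else truth.beta_fit
    )
    vol = (
        truth.mu.to_numpy()[None, :]
        + np.outer(age_c, beta_age.to_numpy())
        + np.outer(fit_c, beta_fit.to_numpy())
        + np.outer(etiv - etiv.mean(), gamma)
        + rng.normal(0, spec.noise_sd, size=(n, len(regions)))
    )
    vol = np.clip(vol, 1.0, None)
    bilat = pd.DataFrame(
        vol, index=pd.Index([f"ref-{i:02d}" for i in range(n)], name="id"),
        columns=regions,
    )
    native = pd.DataFrame(index=bilat.index)
    for region in regions:
        if region in atlas.paired_regions:
            asym = rng.normal(0, spec.hemi_asym_sd, n)
            native[f"lh_{region}"] = bilat[region] / 2 + asym
            native[f"rh_{region}"] = bilat[region] / 2 - asym
        else:
            native[region] = bilat[region]
    native["etiv"] = etiv
    native["role"] = "reference"
    return native


def write_fixture_freesurfer_stats(
    table: pd.DataFrame, out_dir: str | Path, atlas: ROIAtlas | None = None
) -> list[Path]:
    """Write per-participant aseg/aparc-dialect .stats files.

    Produces ``<id>/aseg.stats``, ``<id>/lh.aparc.stats`` and
    ``<id>/rh.aparc.stats`` that :func:`agefit.volumes.read_freesurfer_stats`
    round-trips exactly (volumes are written in full float precision).
    """
    atlas = atlas or load_atlas()
    out_dir = Path(out_dir)
    info = atlas.table.set_index("region")
    written: list[Path] = []
    for pid, row in table.iterrows():
        d = out_dir / str(pid)
        d.mkdir(parents=True, exist_ok=True)
        aseg_lines = [
            "# Title Segmentation Statistics",
            f"# Measure EstimatedTotalIntraCranialVol, eTIV, Estimated Total "
            f"Intracranial Volume, {row['etiv']!r}, mm^3",
            "# ColHeaders Index SegId NVoxels Volume_mm3 StructName",
        ]
        aparc: dict[str, list[str]] = {
            h: [
                "# Title Parcellation Statistics",
                f"# Measure EstimatedTotalIntraCranialVol, eTIV, Estimated Total "
                f"Intracranial Volume, {row['etiv']!r}, mm^3",
                "# ColHeaders StructName NumVert SurfArea GrayVol",
            ]
            for h in ("lh", "rh")
        }
        idx = 1
        for region in atlas.regions:
            fs = str(info.loc[region, "fs_name"])
            paired = bool(info.loc[region, "paired"])
            cortical = fs.islower()
            if cortical:
                for h in ("lh", "rh"):
                    v = row[f"{h}_{region}"]
                    aparc[h].append(f"{fs}  1000  600  {v!r}")
            elif paired:
                for h, pre in (("lh", "Left-"), ("rh", "Right-")):
                    v = row[f"{h}_{region}"]
                    aseg_lines.append(f"{idx}  {idx}  1000  {v!r}  {pre}{fs}")
                    idx += 1
            else:
                v = row[region]
                aseg_lines.append(f"{idx}  {idx}  1000  {v!r}  {fs}")
                idx += 1
        for fname, lines in (
            ("aseg.stats", aseg_lines),
            ("lh.aparc.stats", aparc["lh"]),
            ("rh.aparc.stats", aparc["rh"]),
        ):
            path = d / fname
            path.write_text("\n".join(lines) + "\n")
            written.append(path)
    return written
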