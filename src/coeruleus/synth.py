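"""Synthetic data with known ground truth.

Three generators emulate the inputs of the analysis without any download:

* ``make_nm_phantom`` — a neuromelanin-sensitive 3D volume: hyperintense
  nuclei (locus coeruleus, VTA/SNc) as smooth Gaussian bumps over a flat
  background, a white-matter control region at background intensity, and
  additive Gaussian noise.  An optional additive shift of the LC amplitude
  models the group effect in cocaine users.
* ``make_bold_run`` — a block-design BOLD run: a seed region whose neural
  signal drives target voxels with condition-dependent coupling (the
  generative premise of gPPI), convolved with the canonical HRF, plus a
  physiological sinusoid, motion-locked nuisance signal and white noise.
* ``make_cohort`` — per-subject covariates mirroring the demographics
  table (age, sex, AUDIT, FTND), craving (CCQ) scores drawn with a
  controllable correlation to the true per-subject coupling contrast, and
  per-subject seeds for the other two generators.

Defaults follow the acquisition described for the study: TR = 1 s, two
conditions in alternating ~45 s blocks (2 s fixation + six 6 s pictures),
six blocks per condition and run; CCQ marginal 40.0 +/- 16.2; cohort sizes
44 users / 59 controls.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .glm import BlockSchedule, Hrf
from .gppi import hrf_matrix


# ---------------------------------------------------------------------------
# Neuromelanin phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NucleusDef:
    """Center (voxel index), Gaussian decay scale (mm), template radius
    (mm) and hyperintensity amplitude multiplier of one nucleus."""
    center: tuple[int, int, int]
    decay_mm: float
    template_radius_mm: float
    amplitude: float


@dataclass(frozen=True)
class NmPhantomParams:
    """Neuromelanin phantom: grid, nuclei, control region, noise.

    The volume is ``background * (1 + sum of truncated Gaussian bumps)``
    plus N(0, noise_sd) noise.  ``lc_group_effect`` is added to the LC
    amplitude for subjects in the user group only.
    """

    shape: tuple[int, int, int] = (16, 48, 48)       # (k, j, i)
    voxel_size: tuple[float, float, float] = (2.0, 0.5, 0.5)  # mm
    background: float = 100.0
    nuclei: dict[str, NucleusDef] = field(default_factory=lambda: {
        "lc": NucleusDef(center=(8, 12, 14), decay_mm=1.2,
                         template_radius_mm=1.0, amplitude=1.15),
        "vta_snc": NucleusDef(center=(8, 12, 34), decay_mm=1.8,
                              template_radius_mm=1.8, amplitude=1.10),
    })
    control_box: tuple[slice, slice, slice] = (
        slice(6, 11), slice(36, 42), slice(16, 32))
    noise_sd: float = 2.0
    lc_group_effect: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        vz = np.asarray(self.voxel_size, dtype=float)
        for name, nuc in self.nuclei.items():
            if nuc.amplitude < 1.0:
                raise ValueError(f"amplitude of {name!r} must be >= 1")
            c = np.asarray(nuc.center, dtype=float)
            r_vox = 3.0 * nuc.decay_mm / vz       # truncation radius
            if np.any(c - r_vox < 0) or \
                    np.any(c + r_vox > np.asarray(self.shape) - 1):
                raise ValueError(
                    f"nucleus {name!r} extends outside the grid")


def _distance_mm(shape, voxel_size, center) -> np.ndarray:
    axes = [ (np.arange(n) - c) * v
             for n, v, c in zip(shape, voxel_size, center)]
    kk, jj, ii = np.meshgrid(*axes, indexing="ij")
    return np.sqrt(kk ** 2 + jj ** 2 + ii ** 2)


@dataclass
class NmGroundTruth:
    """Noise-free reference for one phantom."""
    templates: dict[str, np.ndarray]
    control: np.ndarray
    centers: dict[str, tuple[int, int, int]]
    amplitudes: dict[str, float]
    noise_free: np.ndarray
    peak_values: dict[str, float]
    true_peak_contrast: dict[str, float]   # (A*bg - bg)/(A*bg + bg)


def make_nm_phantom(params: NmPhantomParams, group: str = "control"
                    ) -> tuple[np.ndarray, NmGroundTruth]:
    """Generate one neuromelanin phantom volume plus its ground truth.

    ``group='user'`` adds ``lc_group_effect`` to the LC amplitude.
    """
    if group not in ("control", "user"):
        raise ValueError("group must be 'control' or 'user'")
    rng = np.random.default_rng(params.seed)
    bg = params.background
    vol = np.full(params.shape, 1.0)
    gt = NmGroundTruth(templates={}, control=np.zeros(params.shape, bool),
                       centers={}, amplitudes={}, noise_free=None,
                       peak_values={}, true_peak_contrast={})
    for name, nuc in params.nuclei.items():
        amp = nuc.amplitude
        if name == "lc" and group == "user":
            amp = amp + params.lc_group_effect
        d = _distance_mm(params.shape, params.voxel_size, nuc.center)
        bump = (amp - 1.0) * np.exp(-d ** 2 / (2.0 * nuc.decay_mm ** 2))
        bump[d > 3.0 * nuc.decay_mm] = 0.0
        vol += bump
        gt.templates[name] = d <= nuc.template_radius_mm
        gt.centers[name] = nuc.center
        gt.amplitudes[name] = amp
        gt.peak_values[name] = bg * amp
        gt.true_peak_contrast[name] = (amp - 1.0) / (amp + 1.0)
    vol *= bg
    gt.control[params.control_box] = True
    gt.noise_free = vol.copy()
    if params.noise_sd > 0:
        vol = vol + rng.normal(0.0, params.noise_sd, size=params.shape)
    return vol, gt


# ---------------------------------------------------------------------------
# BOLD simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoldSimParams:
    """Block-design BOLD generative model.

    Target neural signal per voxel v:

        n_v(t) = baseline + w_v * [task_amp * (box_d + box_n)
                                   + drug_activation * box_d]
                 + w_v * [gamma_baseline * seed_neural(t)
                          + sum_c gamma_c * seed_neural(t) * box_c(t)]

    with ``w_v`` a smooth blob weight (1 at the blob center, ~0 outside).
    Neural signals are convolved with the canonical HRF; a physiological
    sinusoid, motion-locked signal and white noise are added afterwards.
    """

    tr: float = 1.0
    n_scans: int = 540
    n_blocks: int = 6
    block_cycle: float = 45.0
    fixation: float = 2.0
    picture_duration: float = 36.0
    baseline: float = 0.0
    task_amp: float = 1.0
    drug_activation: float = 0.5
    gamma_drug: float = 0.8
    gamma_neutral: float = 0.2
    gamma_baseline: float = 0.0     # condition-independent coupling
    physio_freq: float = 0.3
    physio_amp: float = 0.5
    noise_sd: float = 0.5
    motion_amp: float = 0.1
    seed_fluct_sd: float = 1.0
    target_shape: tuple[int, int, int] = (6, 6, 6)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("repetition time must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if 2 * self.n_blocks * self.block_cycle > self.n_scans * self.tr:
            raise ValueError("block schedule does not fit the scan count")
        if self.physio_amp != 0 and not \
                (0.0 < self.physio_freq < 0.5 / self.tr):
            raise ValueError("physiological frequency must be below "
                             "Nyquist")

    def schedule(self) -> BlockSchedule:
        return BlockSchedule.alternating(
            n_blocks=self.n_blocks, block_cycle=self.block_cycle,
            fixation=self.fixation, picture_duration=self.picture_duration)


def blob_weights(shape: tuple[int, int, int]) -> np.ndarray:
    """Smooth coupling/activation weight field: Gaussian bump centered in
    the grid, peak exactly 1 at the central voxel."""
    center = [(n - 1) / 2.0 for n in shape]
    axes = [np.arange(n) - c for n, c in zip(shape, center)]
    kk, jj, ii = np.meshgrid(*axes, indexing="ij")
    d2 = kk ** 2 + jj ** 2 + ii ** 2
    sigma = max(min(shape) / 4.0, 1.0)
    w = np.exp(-d2 / (2.0 * sigma ** 2))
    return w / w.max()


def blob_mask(shape: tuple[int, int, int], fraction: float) -> np.ndarray:
    """Voxels whose blob weight reaches ``fraction`` of its peak."""
    w = blob_weights(shape)
    return w >= fraction * w.max()


@dataclass
class BoldRun:
    seed_series: np.ndarray       # T
    targets: np.ndarray           # T x V (C-order raveled target grid)
    motion: np.ndarray            # T x 6
    tr: float
    target_shape: tuple[int, int, int]
    schedule: BlockSchedule


@dataclass
class BoldGroundTruth:
    seed_neural: np.ndarray
    indicators: dict[str, np.ndarray]
    weights: np.ndarray           # blob weight per target voxel (V,)
    gamma: dict[str, float]
    physio_phase: float


def make_bold_run(params: BoldSimParams, hrf: Hrf | None = None
                  ) -> tuple[BoldRun, BoldGroundTruth]:
    """Simulate one block-design run (seed + target voxels)."""
    rng = np.random.default_rng(params.seed)
    hrf = hrf or Hrf()
    T = params.n_scans
    tr = params.tr
    sched = params.schedule()
    box = {c: sched.indicator(tr, T, c) for c in sched.conditions}
    t = np.arange(T) * tr

    # seed neural signal: baseline + task + AR(1) fluctuation
    fluct = np.zeros(T)
    if params.seed_fluct_sd > 0:
        innov = rng.normal(0.0, params.seed_fluct_sd, size=T)
        phi = 0.5
        for i in range(1, T):
            fluct[i] = phi * fluct[i - 1] + innov[i]
        fluct *= np.sqrt(1 - phi ** 2)   # keep marginal sd ~ seed_fluct_sd
    seed_neural = params.baseline \
        + params.task_amp * (box["drug"] + box["neutral"]) + fluct

    w = blob_weights(params.target_shape).ravel()
    V = w.size
    gamma = {"drug": params.gamma_drug, "neutral": params.gamma_neutral}
    task = params.task_amp * (box["drug"] + box["neutral"]) \
        + params.drug_activation * box["drug"]
    coupling = sum(g * seed_neural * box[c] for c, g in gamma.items()) \
        + params.gamma_baseline * seed_neural
    # T x V neural matrix
    neural = params.baseline + np.outer(task + coupling, w)

    H = hrf_matrix(T, tr, hrf)
    seed_bold = H @ seed_neural
    target_bold = H @ neural

    phase = float(rng.uniform(0, 2 * np.pi))
    if params.physio_amp != 0:
        physio = params.physio_amp * np.sin(
            2 * np.pi * params.physio_freq * t + phase)
        seed_bold = seed_bold + physio
        target_bold = target_bold + physio[:, None]

    motion = np.cumsum(rng.normal(0.0, 0.02, size=(T, 6)), axis=0)
    if params.motion_amp != 0:
        wv = rng.normal(0.0, 1.0, size=(6, V))
        target_bold = target_bold + params.motion_amp * (motion @ wv)
        seed_bold = seed_bold + params.motion_amp \
            * (motion @ rng.normal(0.0, 1.0, size=6))

    if params.noise_sd > 0:
        seed_bold = seed_bold + rng.normal(0.0, params.noise_sd, size=T)
        target_bold = target_bold + rng.normal(0.0, params.noise_sd,
                                               size=(T, V))

    run = BoldRun(seed_series=seed_bold, targets=target_bold,
                  motion=motion, tr=tr, target_shape=params.target_shape,
                  schedule=sched)
    gt = BoldGroundTruth(seed_neural=seed_neural, indicators=box,
                         weights=w, gamma=gamma, physio_phase=phase)
    return run, gt


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupMoments:
    """Mean/sd pairs per group (user, control)."""
    user: tuple[float, float]
    control: tuple[float, float]


@dataclass(frozen=True)
class CohortParams:
    """Cohort composition, covariate distributions and the target
    correlation between true coupling contrast and craving score.

    Defaults reproduce the demographics table: 44 users / 59 controls,
    age 46.5 +/- 7.2 vs 43.7 +/- 9.8, 7/44 vs 15/59 women, AUDIT
    4.8 +/- 5.7 vs 3.7 +/- 4.3, FTND 3.6 +/- 2.8 vs 0.3 +/- 1.2, and a
    CCQ marginal of 40.0 +/- 16.2.  Per-subject coupling contrasts
    (gamma_drug - gamma_neutral) are normal around the BOLD parameter
    defaults; craving is drawn jointly with the requested correlation.
    """

    n_user: int = 44
    n_control: int = 59
    age: GroupMoments = GroupMoments((46.5, 7.2), (43.7, 9.8))
    female_prop: tuple[float, float] = (7 / 44, 15 / 59)
    audit: GroupMoments = GroupMoments((4.8, 5.7), (3.7, 4.3))
    ftnd: GroupMoments = GroupMoments((3.6, 2.8), (0.3, 1.2))
    ccq_mean: float = 40.0
    ccq_sd: float = 16.2
    target_corr: float = 0.44
    coupling_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_user, self.n_control) < 2:
            raise ValueError("need n >= 2 per group")
        if not -1.0 <= self.target_corr <= 1.0:
            raise ValueError("target correlation must lie in [-1, 1]")


@dataclass
class SubjectRecord:
    """One synthetic subject: covariates, ground truth and the seeded
    generator parameters for their images."""

    subject_id: str
    group: str                      # "user" | "control"
    age: float
    sex: int                        # female = 1
    audit: float
    ftnd: float
    ccq: float
    true_coupling_contrast: float
    nm_params: NmPhantomParams
    bold_params: BoldSimParams

    def make_nm(self) -> tuple[np.ndarray, NmGroundTruth]:
        return make_nm_phantom(self.nm_params, group=self.group)

    def make_bold(self) -> tuple[BoldRun, BoldGroundTruth]:
        return make_bold_run(self.bold_params)


def make_cohort(params: CohortParams,
                nm: NmPhantomParams | None = None,
                bold: BoldSimParams | None = None,
                out_dir: str | Path | None = None) -> list[SubjectRecord]:
    """Draw a cohort of subject records (optionally writing files).

    The per-subject true coupling contrast and CCQ score come from a
    bivariate normal with correlation ``target_corr``; the LC group effect
    is applied inside ``make_nm_phantom`` for the user group only.
    """
    nm = nm or NmPhantomParams()
    bold = bold or BoldSimParams()
    rng = np.random.default_rng(params.seed)
    mean_contrast = bold.gamma_drug - bold.gamma_neutral
    records: list[SubjectRecord] = []
    counts = {"user": params.n_user, "control": params.n_control}
    idx = 0
    for group in ("user", "control"):
        for _ in range(counts[group]):
            idx += 1
            u, v = rng.normal(size=2)
            contrast = mean_contrast + params.coupling_sd * u
            r = params.target_corr
            ccq = params.ccq_mean + params.ccq_sd * (
                r * u + np.sqrt(1.0 - r ** 2) * v)
            gm = getattr(params.age, group)
            age = rng.normal(*gm)
            sex = int(rng.random() <
                      params.female_prop[0 if group == "user" else 1])
            audit = max(rng.normal(*getattr(params.audit, group)), 0.0)
            ftnd = max(rng.normal(*getattr(params.ftnd, group)), 0.0)
            nm_seed = int(rng.integers(0, 2 ** 31 - 1))
            bold_seed = int(rng.integers(0, 2 ** 31 - 1))
            records.append(SubjectRecord(
                subject_id=f"sub-{idx:04d}", group=group, age=float(age),
                sex=sex, audit=float(audit), ftnd=float(ftnd),
                ccq=float(ccq), true_coupling_contrast=float(contrast),
                nm_params=dataclasses.replace(nm, seed=nm_seed),
                bold_params=dataclasses.replace(
                    bold, seed=bold_seed,
                    gamma_drug=bold.gamma_neutral + float(contrast))))
    if out_dir is not None:
        write_cohort(records, out_dir)
    return records


def covariate_table(records: list[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "subject_id": r.subject_id, "group": r.group, "age": r.age,
        "sex": r.sex, "audit": r.audit, "ftnd": r.ftnd, "ccq": r.ccq,
    } for r in records])


def write_cohort(records: list[SubjectRecord], out_dir: str | Path
                 ) -> Path:
    """Write NIfTI volumes, the covariate TSV and ground-truth sidecars."""
    import nibabel as nib
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    covariate_table(records).to_csv(out / "participants.tsv", sep="\t",
                                    index=False)
    for r in records:
        sub = out / r.subject_id
        sub.mkdir(exist_ok=True)
        vol, gt = r.make_nm()
        vz = r.nm_params.voxel_size
        affine = np.diag([vz[0], vz[1], vz[2], 1.0])
        nib.save(nib.Nifti1Image(vol.astype(np.float32), affine),
                 sub / "nm.nii.gz")
        for name, tpl in gt.templates.items():
            nib.save(nib.Nifti1Image(tpl.astype(np.uint8), affine),
                     sub / f"template_{name}.nii.gz")
        nib.save(nib.Nifti1Image(gt.control.astype(np.uint8), affine),
                 sub / "template_control.nii.gz")
        run, bgt = r.make_bold()
        T = run.targets.shape[0]
        bold4d = run.targets.T.reshape(run.target_shape + (T,))
        nib.save(nib.Nifti1Image(bold4d.astype(np.float32), np.eye(4)),
                 sub / "bold.nii.gz")
        np.savetxt(sub / "motion.tsv", run.motion, delimiter="\t")
        pd.DataFrame({
            "seed": run.seed_series}).to_csv(sub / "seed.tsv", sep="\t",
                                             index=False)
        events = []
        for c in run.schedule.conditions:
            for o, d in zip(run.schedule.onsets[c],
                            run.schedule.durations[c]):
                events.append({"onset": float(o), "duration": float(d),
                               "condition": c})
        pd.DataFrame(events).sort_values("onset").to_csv(
            sub / "events.tsv", sep="\t", index=False)
        sidecar = {
            "subject_id": r.subject_id, "group": r.group,
            "true_coupling_contrast": r.true_coupling_contrast,
            "gamma": bgt.gamma,
            "nm_seed": r.nm_params.seed, "bold_seed": r.bold_params.seed,
            "true_peak_contrast": gt.true_peak_contrast,
        }
        (sub / "ground_truth.json").write_text(
            json.dumps(sidecar, indent=2))
    return out
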