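"""Configuration and the end-to-end runner.

``run_all`` ties the stages together on a synthetic cohort: simulate ->
neuromelanin quantification -> physiological-noise separation of the seed
series -> first-level cue-reactivity GLM -> gPPI -> group and correlation
statistics.  Every output file carries a hash of the resolved
configuration; results are deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import glm, gppi, nms, physio, stats, synth

DEFAULT_FRACTIONS = (0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass
class AnalysisOptions:
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS
    lc_layers: int = 3
    vta_layers: int = 1
    connectivity: int = 6
    high_pass: float = 128.0
    deconv_lambda: float | None = None     # None -> GCV on first subject
    n_perm: int = 200
    voxel_p: float = 0.001
    physio_band: tuple[float, float] = (0.2, 0.5)
    clean_physio: bool = True

    def validate(self) -> None:
        for f in self.fractions:
            if not 0.0 < f <= 1.0:
                raise ValueError(f"analysis.fractions: {f} out of (0, 1]")
        if self.connectivity not in (6, 26):
            raise ValueError("analysis.connectivity must be 6 or 26")
        if not 0.0 < self.voxel_p < 1.0:
            raise ValueError("analysis.voxel_p out of (0, 1)")
        if self.n_perm < 100:
            raise ValueError("analysis.n_perm must be >= 100")
        if min(self.lc_layers, self.vta_layers) < 0:
            raise ValueError("dilation layers must be >= 0")


@dataclass
class RunConfig:
    out_dir: str = "results"
    seed: int = 0
    overwrite: bool = False
    cohort: synth.CohortParams = field(default_factory=synth.CohortParams)
    nm: synth.NmPhantomParams = field(
        default_factory=synth.NmPhantomParams)
    bold: synth.BoldSimParams = field(default_factory=synth.BoldSimParams)
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)

    def resolved(self) -> dict:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return {k: enc(v) for k, v in
                        dataclasses.asdict(o).items()}
            if isinstance(o, dict):
                return {k: enc(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [enc(v) for v in o]
            if isinstance(o, slice):
                return [o.start, o.stop, o.step]
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            return o
        return enc(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.resolved(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


_SECTION_TYPES = {
    "cohort": synth.CohortParams,
    "nm": synth.NmPhantomParams,
    "bold": synth.BoldSimParams,
    "analysis": AnalysisOptions,
}


def _build_section(cls, data: dict, section: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown key(s) in {section!r}: "
                         + ", ".join(sorted(unknown)))
    kw = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if f.name == "nuclei" and isinstance(v, dict):
            v = {k: synth.NucleusDef(center=tuple(d["center"]),
                                     decay_mm=d["decay_mm"],
                                     template_radius_mm=
                                     d["template_radius_mm"],
                                     amplitude=d["amplitude"])
                 if isinstance(d, dict) else d for k, d in v.items()}
        elif f.name == "control_box" and isinstance(v, (list, tuple)):
            v = tuple(s if isinstance(s, slice) else slice(*s) for s in v)
        elif isinstance(v, dict) and set(v) == {"user", "control"}:
            v = synth.GroupMoments(user=tuple(v["user"]),
                                   control=tuple(v["control"]))
        elif isinstance(v, list):
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        kw[f.name] = v
    return cls(**kw)


def validate_config(path: str | Path | None = None,
                    data: dict | None = None) -> RunConfig:
    """Parse and fully resolve a YAML run configuration.

    Unknown keys are a hard error; section dataclasses perform their own
    range validation on construction.
    """
    if data is None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
    else:
        raw = dict(data)
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    top_valid = {"out_dir", "seed", "overwrite", *_SECTION_TYPES}
    unknown = set(raw) - top_valid
    if unknown:
        raise ValueError("unknown key(s): " + ", ".join(sorted(unknown)))
    kw = {}
    for key in ("out_dir", "seed", "overwrite"):
        if key in raw:
            kw[key] = raw[key]
    for section, cls in _SECTION_TYPES.items():
        sec = raw.get(section, {})
        if not isinstance(sec, dict):
            raise ValueError(f"section {section!r} must be a mapping")
        kw[section] = _build_section(cls, sec, section)
    cfg = RunConfig(**kw)
    cfg.analysis.validate()
    return cfg


def dump_config(cfg: RunConfig, path: str | Path) -> Path:
    """Write the fully-resolved configuration as YAML; the result is
    accepted unchanged by ``validate_config``."""
    path = Path(path)
    path.write_text(yaml.safe_dump(cfg.resolved(), sort_keys=True))
    return path


def _write_csv(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, index=False)


def _analyze_subject(rec: synth.SubjectRecord, cfg: RunConfig,
                     lam: float) -> dict:
    opts = cfg.analysis
    vol, gt = rec.make_nm()
    out = {"nms": {}, "record": rec}
    for name, layers in (("lc", opts.lc_layers),
                         ("vta_snc", opts.vta_layers)):
        spec = nms.NucleusSpec(template=gt.templates[name],
                               control=gt.control, layers=layers,
                               name=name, connectivity=opts.connectivity)
        out["nms"][name] = nms.compute_nms_profile(vol, spec,
                                                   opts.fractions)
    run, _bgt = rec.make_bold()
    T = run.targets.shape[0]
    seed_series = run.seed_series
    if opts.clean_physio:
        freqs = physio.estimate_frequency_trajectory(
            seed_series, run.tr, opts.physio_band)
        # resonator model needs strictly sub-Nyquist frequencies
        freqs = np.clip(freqs, None, 0.499 / run.tr)
        model = physio.OscillatorModel(
            freqs=freqs, tr=run.tr,
            q_walk=max(np.var(seed_series), 1e-6) * 1e-2,
            q_osc=max(np.var(seed_series), 1e-6) * 1e-2,
            r_meas=max(np.var(seed_series), 1e-6) * 1e-1)
        sep = physio.separate_signal(seed_series, model)
        seed_series = sep.cleaned + sep.residual
    design = glm.build_design(run.schedule, run.tr, T,
                              nuisance=run.motion,
                              high_pass=opts.high_pass)
    fit = glm.fit_glm_ar1(run.targets, design)
    w = glm.contrast_weights(design, "drug", "neutral")
    out["activation_con"] = glm.contrast(fit, w)
    seed_centered = seed_series - seed_series.mean()
    neural = gppi.deconvolve(seed_centered, run.tr, lam=lam)
    ppi = gppi.build_ppi(neural, seed_centered, run.schedule, run.tr, T,
                         lam=lam)
    gfit = gppi.fit_gppi(run.targets, ppi, nuisance=run.motion)
    out["gppi_con"] = gfit.contrast
    out["gppi_roi"] = {
        f: glm.roi_mean(gfit.contrast.reshape(run.target_shape),
                        synth.blob_mask(run.target_shape, f))
        for f in opts.fractions}
    out["target_shape"] = run.target_shape
    return out


def run_all(config: RunConfig) -> dict:
    """Run the full pipeline on a synthetic cohort; returns the summary.

    Stage order: simulate -> per-subject NMS + first-level GLM + gPPI ->
    group NMS comparison, cluster-FWE activation inference, and the
    gPPI-craving robustness profile.  Outputs land in ``config.out_dir``.
    """
    cfg_hash = config.config_hash()
    out = Path(config.out_dir)
    summary_path = out / "summary.json"
    if summary_path.exists() and not config.overwrite:
        raise FileExistsError(
            f"{summary_path} exists; pass overwrite to replace "
            f"(config hash {cfg_hash})")
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"config_hash={cfg_hash}", f"seed={config.seed}"]
    t0 = time.time()

    cohort_params = dataclasses.replace(config.cohort, seed=config.seed)
    records = synth.make_cohort(cohort_params, nm=config.nm,
                                bold=config.bold)
    synth.covariate_table(records).to_csv(out / "participants.tsv",
                                          sep="\t", index=False)
    log_lines.append(f"simulate: n={len(records)} "
                     f"({time.time() - t0:.1f}s)")

    lam = config.analysis.deconv_lambda
    if lam is None:
        run0, _ = records[0].make_bold()
        lam = gppi.gcv_lambda(run0.seed_series - run0.seed_series.mean(),
                              run0.tr)
        log_lines.append(f"gcv lambda={lam:.4g}")

    t1 = time.time()
    subj = [_analyze_subject(r, config, lam) for r in records]
    log_lines.append(f"subjects: ({time.time() - t1:.1f}s)")

    nms_rows = []
    for s in subj:
        for name, prof in s["nms"].items():
            df = prof.to_frame(subject=s["record"].subject_id)
            df["group"] = s["record"].group
            nms_rows.append(df)
    nms_df = pd.concat(nms_rows, ignore_index=True)
    _write_csv(nms_df, out / "nms.csv", cfg_hash)

    covs = pd.DataFrame([{"age": r.age, "sex": r.sex, "audit": r.audit,
                          "ftnd": r.ftnd} for r in records])
    group_vec = np.array([1 if r.group == "user" else 0 for r in records])
    group_rows = []
    for name in ("lc", "vta_snc"):
        for f in config.analysis.fractions:
            vals = np.array([s["nms"][name].contrast[f] for s in subj])
            res = stats.adjusted_group_difference(vals, group_vec, covs)
            group_rows.append({"nucleus": name, "fraction": f,
                               "t": res.statistic, "p": res.p,
                               "df": res.df})
    group_df = pd.DataFrame(group_rows)
    _write_csv(group_df, out / "group_nms.csv", cfg_hash)

    users = [s for s in subj if s["record"].group == "user"]
    shape = users[0]["target_shape"]
    cons = np.stack([s["activation_con"] for s in users])
    clusters = glm.cluster_fwe(cons, shape,
                               voxel_p=config.analysis.voxel_p,
                               n_perm=config.analysis.n_perm,
                               seed=config.seed)
    _write_csv(clusters.assign(peak=clusters["peak"].astype(str))
               if len(clusters) else clusters,
               out / "clusters.csv", cfg_hash)

    roi_df = pd.DataFrame([
        {"subject": s["record"].subject_id,
         **{f"f{f:.1f}": s["gppi_roi"][f]
            for f in config.analysis.fractions}}
        for s in users])
    _write_csv(roi_df, out / "gppi_roi.csv", cfg_hash)

    user_covs = covs[group_vec == 1].reset_index(drop=True)
    ccq = np.array([s["record"].ccq for s in users])
    measures = {f: np.array([s["gppi_roi"][f] for s in users])
                for f in config.analysis.fractions}
    profile = stats.robustness_profile(measures, ccq, user_covs)
    _write_csv(profile.to_frame(), out / "stats_robustness.csv", cfg_hash)

    summary = {
        "config_hash": cfg_hash,
        "seed": config.seed,
        "n_user": int(group_vec.sum()),
        "n_control": int((1 - group_vec).sum()),
        "group_nms": group_rows,
        "n_fwe_clusters": int((clusters["p_fwe"] <= 0.05).sum())
        if len(clusters) else 0,
        "clusters": clusters.assign(
            peak=clusters["peak"].astype(str)).to_dict("records")
        if len(clusters) else [],
        "gppi_craving": profile.to_frame().to_dict("records"),
    }
    summary_path.write_text(json.dumps(summary, indent=2))
    log_lines.append(f"total: ({time.time() - t0:.1f}s)")
    (out / "log.txt").write_text("\n".join(log_lines) + "\n")
    return summary
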