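"""Pipeline orchestration: simulate -> ksi -> harmonize -> uncertainty ->
select-model -> trajectories, with a self-describing manifest.

Every stage reads and writes plain CSV/JSON files in the run directory.
The manifest echoes the full configuration (defaults included), the root
seed, the package version, a checksum for every output file and all
warnings surfaced by the stages, so a run can be audited and reproduced
bit-identically from its manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .data_model import PRIMARY_VARIABLES, read_morph_table, records_to_frame, write_morph_table
from .evidence import MODEL_IDS, compare_models, extract_sample_data, log_marginal_likelihood, make_trend_model
from .folding_geometry import DEFAULT_S_VARIANT, add_folding_columns
from .harmonization import fit_joint_trend, fit_primary_trends, harmonize_primary
from .synthetic_cohort import (
    CohortSpec,
    default_cohort_spec,
    generate_cohort,
    generate_repeats,
    ksi_trend_spec,
    recovery_cohort_spec,
)
from .trajectories import alpha_by_decade, baseline_table, compare_slopes, fit_trajectories
from .uncertainty_budget import build_budget, propagate_repeats_to_ksi, repeats_sd_for_variable

logger = logging.getLogger(__name__)

KSI_VARIABLES = ("K", "S", "I", "GI")
_SCENARIOS = {
    "default": default_cohort_spec,
    "recovery": recovery_cohort_spec,
    "ksi_trend": ksi_trend_spec,
}


@dataclass
class RunConfig:
    """Everything a full pipeline run depends on; YAML-loadable."""

    out_dir: str
    seed: int = 0
    input_csv: str | None = None  # None -> simulate `scenario`
    scenario: str = "default"  # builder name or path to a CohortSpec YAML
    s_variant: str = DEFAULT_S_VARIANT
    roi_interaction: bool | None = None
    ctl_only: bool = True
    strict_read: bool = False
    evidence_variable: str = "avg_thickness_mm"
    evidence_models: tuple = MODEL_IDS
    evidence_nodes: int = 32
    evidence_roi: str = "hemisphere"
    adjustment: str = "tukey"
    min_n: int = 10
    reference_age: float | None = None
    n_repeats: int = 3
    n_repeat_subjects: int = 50

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["evidence_models"] = list(self.evidence_models)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "evidence_models" in d:
            d["evidence_models"] = tuple(d["evidence_models"])
        return cls(**d)

    def resolve_spec(self) -> CohortSpec:
        if self.scenario in _SCENARIOS:
            return _SCENARIOS[self.scenario](seed=self.seed)
        return CohortSpec.from_yaml(self.scenario)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory.

    On stage failure the manifest records the stages completed so far
    before the exception propagates.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "version": __version__,
        "stages": [],
        "warnings": [],
        "files": {},
    }

    def _finish(path: Path):
        for f in sorted(out.iterdir()):
            if f.is_file() and f.name != "manifest.json":
                manifest["files"][f.name] = _sha256(f)
        _write_json(path, manifest)

    manifest_path = out / "manifest.json"
    try:
        # -- stage 1: cohort ------------------------------------------------
        if config.input_csv is not None:
            if not Path(config.input_csv).exists():
                raise FileNotFoundError(f"input CSV not found: {config.input_csv}")
            records, report = read_morph_table(config.input_csv, strict=config.strict_read)
            cohort = records_to_frame(records)
            _write_json(out / "validation.json", report.to_dict())
            repeats = None
        else:
            spec = config.resolve_spec()
            cohort, truth = generate_cohort(spec, seed=config.seed)
            _write_json(
                out / "truth.json",
                {
                    "seed": truth.seed,
                    "offsets": {"||".join(k): v for k, v in truth.offsets.items()},
                    "slopes": {"||".join(k): v for k, v in truth.slopes.items()},
                    "sigma_natural": truth.sigma_natural,
                    "sigma_random": truth.sigma_random,
                    "sigma_sample": truth.sigma_sample,
                    "sample_sigma_natural": truth.sample_sigma_natural,
                },
            )
            repeats = generate_repeats(
                spec, n_repeats=config.n_repeats, n_subjects=config.n_repeat_subjects,
                seed=config.seed,
            )
            repeats.to_csv(out / "repeats.csv", index=False, float_format="%.12g")
        write_morph_table(cohort, out / "cohort.csv")
        manifest["stages"].append("cohort")

        # -- stage 2: folding coordinates -----------------------------------
        ksi_raw = add_folding_columns(cohort, s_variant=config.s_variant)
        ksi_raw.to_csv(out / "ksi.csv", index=False, float_format="%.12g")
        manifest["stages"].append("ksi")

        # -- stage 3: harmonization -----------------------------------------
        fits = fit_primary_trends(
            cohort, use_roi_interaction=config.roi_interaction, ctl_only=config.ctl_only
        )
        _write_json(out / "fits.json", {v: f.to_dict() for v, f in fits.items()})
        for f in fits.values():
            manifest["warnings"].extend(f"{f.variable}: {w}" for w in f.warnings)
        harmonized = harmonize_primary(cohort, fits)
        harmonized_ksi = add_folding_columns(harmonized, s_variant=config.s_variant)
        harmonized_ksi.to_csv(out / "harmonized.csv", index=False, float_format="%.12g")
        manifest["stages"].append("harmonize")

        # -- stage 4: uncertainty budget ------------------------------------
        if repeats is not None:
            budgets = {}
            for var in PRIMARY_VARIABLES:
                sr = repeats_sd_for_variable(repeats, var, log10=True)
                budgets[var] = build_budget(
                    fits[var], sr, reference_intercept=fits[var].intercept_for_roi(fits[var].reference_roi)
                )
            prop = propagate_repeats_to_ksi(repeats, s_variant=config.s_variant)
            for var in KSI_VARIABLES:
                fit = fit_joint_trend(
                    ksi_raw, var, use_roi_interaction=config.roi_interaction,
                    ctl_only=config.ctl_only, transform="identity",
                )
                sr = repeats_sd_for_variable(prop, var, log10=False)
                budgets[var] = build_budget(
                    fit, sr, reference_intercept=fit.intercept_for_roi(fit.reference_roi)
                )
            _write_json(out / "budget.json", {v: b.to_dict() for v, b in budgets.items()})
            manifest["stages"].append("uncertainty")
        else:
            budgets = {}
            manifest["warnings"].append("no repeats available: uncertainty stage skipped")

        # -- stage 5: trend-model selection ---------------------------------
        data = extract_sample_data(cohort, config.evidence_variable, roi=config.evidence_roi)
        evidences = []
        for mid in config.evidence_models:
            model = make_trend_model(mid, data)
            ev = log_marginal_likelihood(model, data, n_nodes=config.evidence_nodes)
            manifest["warnings"].extend(f"evidence[{mid}]: {w}" for w in ev.warnings)
            evidences.append(ev)
        table = compare_models(evidences)
        _write_json(out / "evidence.json", table.to_dict(orient="records"))
        manifest["stages"].append("select-model")

        # -- stage 6: trajectories ------------------------------------------
        variables = list(PRIMARY_VARIABLES) + list(KSI_VARIABLES)
        traj = fit_trajectories(
            harmonized_ksi, variables, reference_age=config.reference_age
        )
        groups = sorted(harmonized_ksi["group"].unique())
        contrasts = []
        if len(groups) >= 2:
            order = [g for g in ("CTL",) if g in groups] + [g for g in groups if g != "CTL"]
            for var in ("K", "S", "I"):
                contrasts.extend(
                    compare_slopes(harmonized_ksi, var, order, adjustment=config.adjustment)
                )
        decades = alpha_by_decade(harmonized_ksi, min_n=config.min_n)
        baselines = baseline_table(traj, budgets) if budgets else baseline_table(traj, {})
        payload = {
            "trajectories": [dataclasses.asdict(t) for t in traj],
            "contrasts": [dataclasses.asdict(c) for c in contrasts],
            "alpha_by_decade": {
                g: {
                    "min_n": a.min_n,
                    "bins": [
                        {
                            "low": lo, "high": hi, "n": n,
                            "alpha": None if f is None else f.alpha,
                            "ci95": None if f is None else list(f.ci95_alpha),
                        }
                        for lo, hi, n, f in a.bins
                    ],
                    "omitted": [list(o) for o in a.omitted],
                }
                for g, a in decades.items()
            },
            "baselines": [dataclasses.asdict(b) for b in baselines],
        }
        _write_json(out / "trajectories.json", payload)
        manifest["stages"].append("trajectories")
        manifest["completed"] = True
    except Exception as exc:
        manifest["completed"] = False
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        _finish(manifest_path)
        raise
    _finish(manifest_path)
    return out
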