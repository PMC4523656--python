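"""Study orchestration: phantom family x montages -> solve -> metrics -> report.

One *case* is a (phantom, montage) pair: build the phantom (head-only for
intracephalic montages, whole-body when the reference is extracephalic),
place the electrodes, solve for the potential, normalise to the injected
current and derive |E| and |J|.  The study runs every case in the
cross-product, collects per-tissue descriptive statistics and grey/white
focality volumes, computes the coefficient of variability across phantoms
and runs the rank-based model-factor tests on V70 and V50.  Everything is
deterministic: re-running a config reproduces the report byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .conductivity import default_conductivity_table
from .metrics import cv_db, focality_result, tissue_descriptive_stats
from .montage import place_montage, standard_montage
from .nonparam import model_factor_analysis
from .phantom import (AnthropometryParams, build_body_phantom,
                      build_layered_sphere_head, default_profiles)
from .solver import SolvedCase, SolverConfig, solve_montage
from .sphere_oracle import ShellModel

__all__ = ["StudyConfig", "StudyReport", "run_study", "generate_fixtures"]

#: Brain regions reported by the per-tissue statistics.
REPORT_TISSUES = ("brain_grey_matter", "brain_white_matter", "cerebellum",
                  "medulla_oblongata", "pons", "midbrain", "thalamus")
FOCALITY_TISSUES = ("brain_grey_matter", "brain_white_matter")


@dataclass
class StudyConfig:
    """Everything needed to reproduce a study run."""

    profiles: list[AnthropometryParams] = field(default_factory=default_profiles)
    montages: tuple[str, ...] = ("A", "B", "C", "D")
    head_voxel_mm: float = 2.0
    body_voxel_mm: float = 4.0
    injected_current_mA: float = 1.0
    electrode_scale: float = 1.0
    solver: SolverConfig = field(default_factory=SolverConfig)
    tissues: tuple[str, ...] = REPORT_TISSUES
    focality_tissues: tuple[str, ...] = FOCALITY_TISSUES
    robust_peak: bool = False
    alpha: float = 0.05
    out_dir: Path | None = None

    def __post_init__(self):
        if not self.profiles or not self.montages:
            raise ValueError("need at least one phantom profile and one montage")

    def hash(self) -> str:
        blob = json.dumps(
            {"profiles": [asdict(p) for p in self.profiles],
             "montages": list(self.montages),
             "head_voxel_mm": self.head_voxel_mm, "body_voxel_mm": self.body_voxel_mm,
             "current": self.injected_current_mA, "electrode_scale": self.electrode_scale,
             "solver": asdict(self.solver), "tissues": list(self.tissues),
             "focality": list(self.focality_tissues), "robust_peak": self.robust_peak,
             "alpha": self.alpha},
            sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class StudyReport:
    """Tidy tables plus test results and provenance for one study run."""

    tissue_stats: pd.DataFrame     # model, montage, tissue, median..peak, voxel_count
    focality: pd.DataFrame         # model, montage, tissue, v70, v50
    variability: pd.DataFrame      # montage, tissue, statistic, cv_db
    cases: pd.DataFrame            # model, montage, achieved_mA, iterations, residual
    tests: dict
    provenance: dict

    def payload(self) -> dict:
        def tests_dict(t):
            out = {}
            for key, block in t.items():
                out[key] = {
                    "omnibus": asdict(block["omnibus"]),
                    "pairwise": {k: asdict(v) for k, v in block["pairwise"].items()},
                    "alpha": block["alpha"],
                }
            return out

        return {
            "tissue_stats": self.tissue_stats.to_dict(orient="records"),
            "focality": self.focality.to_dict(orient="records"),
            "variability": self.variability.to_dict(orient="records"),
            "cases": self.cases.to_dict(orient="records"),
            "tests": tests_dict(self.tests),
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.payload(), sort_keys=True, indent=1))

    def to_csv_dir(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.tissue_stats.to_csv(out / "tissue_stats.csv", index=False)
        self.focality.to_csv(out / "focality.csv", index=False)
        self.variability.to_csv(out / "variability.csv", index=False)
        self.cases.to_csv(out / "cases.csv", index=False)
        (out / "tests.json").write_text(json.dumps(self.payload()["tests"], sort_keys=True, indent=1))

    def focality_table(self) -> pd.DataFrame:
        """V70/V50 per montage and tissue with one column pair per model."""
        return self.focality.pivot_table(index=["montage", "tissue"], columns="model",
                                         values=["v70", "v50"], sort=True)


def _build_case(profile: AnthropometryParams, montage_name: str, config: StudyConfig) -> SolvedCase:
    spec = standard_montage(montage_name, config.injected_current_mA, config.electrode_scale)
    vox = config.body_voxel_mm if spec.extracephalic else config.head_voxel_mm
    p = AnthropometryParams(**{**asdict(profile), "voxel_size": vox})
    phantom = build_body_phantom(p) if spec.extracephalic else build_layered_sphere_head(p)
    placed = place_montage(phantom, spec)
    return solve_montage(placed, config=config.solver)


def run_study(config: StudyConfig | None = None, progress=None) -> StudyReport:
    """Run the full cross-product study and assemble the report.

    ``progress`` may be a callable taking a status string.  Any stage failure
    aborts with an error naming the stage; partial tables collected so far
    are flushed to ``config.out_dir`` when one is set.
    """
    if config is None:
        config = StudyConfig()
    default_conductivity_table()  # fail early if the shipped table is broken
    stats_rows, foc_rows, case_rows = [], [], []

    def flush():
        if config.out_dir is not None:
            out = Path(config.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            pd.DataFrame(stats_rows).to_csv(out / "partial_tissue_stats.csv", index=False)
            pd.DataFrame(foc_rows).to_csv(out / "partial_focality.csv", index=False)

    for profile in config.profiles:
        for m in config.montages:
            stage = f"{profile.name}/montage-{m}"
            if progress:
                progress(f"solving {stage}")
            try:
                case = _build_case(profile, m, config)
            except Exception as e:
                flush()
                raise RuntimeError(f"stage {stage!r} failed: {e}") from e
            amp = case.E.amplitude()
            labels = case.placed.volume
            for tissue in config.tissues:
                ts = tissue_descriptive_stats(amp, labels.mask(tissue), tissue,
                                              robust_peak=config.robust_peak)
                stats_rows.append({"model": profile.name, "montage": m, **asdict(ts)})
            for tissue in config.focality_tissues:
                fr = focality_result(amp, labels.mask(tissue), tissue,
                                     robust_peak=config.robust_peak)
                foc_rows.append({"model": profile.name, "montage": m, "tissue": tissue,
                                 "v70": fr.v70, "v50": fr.v50})
            case_rows.append({"model": profile.name, "montage": m,
                              "achieved_mA": case.achieved_mA,
                              "solver_method": case.info.method,
                              "iterations": case.info.iterations,
                              "residual": case.info.relative_residual})

    tissue_stats = pd.DataFrame(stats_rows)
    focality = pd.DataFrame(foc_rows)
    cases = pd.DataFrame(case_rows)

    # Variability of peak and median across models, per montage and tissue
    var_rows = []
    model_names = [p.name for p in config.profiles]
    if len(model_names) >= 2:
        for (m, tissue), grp in tissue_stats.groupby(["montage", "tissue"], sort=True):
            for statistic in ("peak", "median"):
                var_rows.append({"montage": m, "tissue": tissue, "statistic": statistic,
                                 "cv_db": cv_db(grp[statistic].to_numpy())})
    variability = pd.DataFrame(var_rows, columns=["montage", "tissue", "statistic", "cv_db"])

    # Model-factor tests on V70 and V50; sampling unit = (montage x tissue)
    tests = {}
    if len(model_names) >= 2 and len(focality) >= 2 * len(model_names):
        for what in ("v70", "v50"):
            groups = {name: focality.loc[focality.model == name, what].tolist()
                      for name in model_names}
            tests[what] = model_factor_analysis(groups, alpha=config.alpha)

    report = StudyReport(
        tissue_stats=tissue_stats, focality=focality, variability=variability,
        cases=cases, tests=tests,
        provenance={"config_hash": config.hash(), "package_version": __version__,
                    "n_cases": len(case_rows)},
    )
    if config.out_dir is not None:
        report.to_csv_dir(config.out_dir)
        report.to_json(Path(config.out_dir) / "report.json")
    return report


# ----------------------------------------------------------------- fixtures

def _montage_spec_json(name: str) -> dict:
    spec = standard_montage(name)
    return {"name": spec.name, "injected_current_mA": spec.injected_current_mA,
            "electrodes": [asdict(e) for e in spec.electrodes]}


def generate_fixtures(out_dir: str | Path, scale: str = "small") -> list[Path]:
    """Write a small, self-contained fixture set (phantoms, montages, shell model).

    ``scale='small'`` produces a head phantom of at most 64^3 voxels that a
    direct solve handles in seconds; ``'default'`` writes the full-size
    adult-female head.  A manifest with SHA-256 checksums lists every file.
    """
    if scale not in ("small", "default"):
        raise ValueError("scale must be 'small' or 'default'")
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as e:
        raise OSError(f"fixture directory {out} is not writable: {e}") from e

    files: list[Path] = []
    if scale == "small":
        # adult-female head at 4 mm: fits in 64^3 yet takes full-size electrodes
        params = AnthropometryParams.scaled_reference("fixture_head", 1.63, voxel_size=4.0)
    else:
        params = AnthropometryParams.scaled_reference("ella_like", 1.63, voxel_size=2.0)
    head = build_layered_sphere_head(params)
    if scale == "small" and max(head.grid.shape) > 64:
        raise AssertionError("small fixture head exceeded 64^3 voxels")
    head_path = out / "head.nii"
    head.to_nifti(head_path)
    files += [head_path, head_path.with_suffix(".json")]

    for m in ("A", "B", "C", "D"):
        p = out / f"montage_{m}.json"
        p.write_text(json.dumps(_montage_spec_json(m), indent=1, sort_keys=True))
        files.append(p)

    shell = ShellModel((46.0, 53.0, 60.0), (0.027512, 0.020028, 0.012147),
                       source=(0.0, 0.0, 1.0),
                       sink=(np.sin(2.0), 0.0, np.cos(2.0)))
    sp = out / "shell_model.json"
    shell.to_json(sp)
    files.append(sp)

    manifest = {
        "scale": scale,
        "files": {f.name: hashlib.sha256(f.read_bytes()).hexdigest() for f in files},
    }
    mp = out / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    files.append(mp)
    return files
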