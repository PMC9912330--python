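"""End-to-end run configuration and pipeline: analyze -> fit -> map."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import scipy
import yaml

from . import __version__
from .binding_fit import global_fit
from .csp_analysis import (
    DEFAULT_N_WEIGHT,
    DEFAULT_TOL_H,
    DEFAULT_TOL_N,
    build_csp_table,
)
from .errors import InvalidParameterError, StageError
from .peaklist_io import read_series
from .site_mapping import find_patches, patch_report_dict, write_structure_map

logger = logging.getLogger("csptitr")


@dataclass
class RunConfig:
    """Validated configuration for one analysis run."""

    manifest: str
    out_dir: str
    protein_conc: float | None = None  # μM; required for the fit stage
    pdb_in: str | None = None
    # CSP-table options
    n_weight: float = DEFAULT_N_WEIGHT
    match_mode: str = "by_label"
    tol_H: float = DEFAULT_TOL_H
    tol_N: float = DEFAULT_TOL_N
    saturated_step: int | None = None
    sigma_k_exclude: float = 3.0
    sigma_about_zero: bool = True
    # fit options
    exclude: list[str] = field(default_factory=list)
    include_overlap: bool = False
    ci_method: str = "covariance"
    ci_level: float = 0.95
    fit_shared_scale: bool = False
    # site-mapping options
    max_gap: int = 1
    # reproducibility
    seed: int = 0

    def validate(self) -> None:
        if not Path(self.manifest).exists():
            raise InvalidParameterError(f"manifest not found: {self.manifest}")
        if self.protein_conc is None:
            raise InvalidParameterError("protein_conc is required")
        if self.protein_conc <= 0:
            raise InvalidParameterError("protein_conc must be > 0")
        if self.n_weight <= 0:
            raise InvalidParameterError("n_weight must be > 0")
        if not 0 <= self.ci_level < 1:
            raise InvalidParameterError("ci_level must be in [0, 1)")
        if self.pdb_in is not None and not Path(self.pdb_in).exists():
            raise InvalidParameterError(f"PDB file not found: {self.pdb_in}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)


def fit_report_dict(fit) -> dict:
    return {
        "K_D_uM": fit.K_D,
        "beta_D": fit.params.beta_D,
        "cal_slope": fit.params.cal_slope,
        "cal_intercept": fit.params.cal_intercept,
        "protein_conc_uM": fit.protein_conc,
        "ci95": fit.ci95,
        "converged": fit.converged,
        "n_points": fit.n_points,
        "dof": fit.dof,
        "sse": fit.sse,
        "labels_used": fit.labels_used,
        "shared_scale": fit.shared_scale,
        "message": fit.message,
    }


def run_pipeline(config: RunConfig) -> Path:
    """Execute analyze -> fit -> map, writing all artifacts into the run directory.

    Every output (CSP table, fit report, patch report, structure map, resolved
    config, log) lands in ``config.out_dir``; errors abort with a
    stage-labelled message and partial outputs are retained.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    (out / "config_resolved.yaml").write_text(yaml.safe_dump(asdict(config), sort_keys=True))
    log_lines = [
        f"csptitr {__version__} | numpy {np.__version__} | scipy {scipy.__version__}",
        f"seed: {config.seed}",
        f"started: {datetime.now(timezone.utc).isoformat()}",
    ]

    try:
        series = read_series(config.manifest)
        csp = build_csp_table(
            series,
            saturated_step=config.saturated_step,
            n_weight=config.n_weight,
            match_mode=config.match_mode,
            tol_H=config.tol_H,
            tol_N=config.tol_N,
            sigma_k_exclude=config.sigma_k_exclude,
            sigma_about_zero=config.sigma_about_zero,
        )
        csp.to_csv(out / "csp_table.csv")
        log_lines.append(
            f"analyze: {len(csp.data)} residues, sigma_c={csp.sigma.sigma_c:.6g} ppm, "
            f"{int(csp.data['significant'].sum())} significant, "
            f"saturation diagnostic {csp.saturation_diagnostic:.6g} ppm"
        )
    except Exception as exc:
        _write_log(out, log_lines + [f"analyze: FAILED ({exc})"])
        raise StageError(f"[analyze] {exc}") from exc

    try:
        fit = global_fit(
            csp,
            series,
            protein_conc=config.protein_conc,
            exclude=set(config.exclude),
            include_overlap=config.include_overlap,
            ci_method=config.ci_method,
            ci_level=config.ci_level,
            fit_shared_scale=config.fit_shared_scale,
            rng=np.random.default_rng(config.seed),
        )
        (out / "fit_report.json").write_text(json.dumps(fit_report_dict(fit), indent=1))
        ci = fit.ci95.get("K_D") if fit.ci95 else None
        log_lines.append(
            f"fit: K_D={fit.K_D:.6g} uM"
            + (f", 95% CI [{ci[0]:.6g}, {ci[1]:.6g}]" if ci else "")
            + f", converged={fit.converged}"
        )
    except Exception as exc:
        _write_log(out, log_lines + [f"fit: FAILED ({exc})"])
        raise StageError(f"[fit] {exc}") from exc

    try:
        report = find_patches(csp, max_gap=config.max_gap)
        (out / "patch_report.json").write_text(
            json.dumps(patch_report_dict(report), indent=1)
        )
        log_lines.append(f"map: {len(report.patches)} patches, "
                         f"{len(report.singletons)} singletons")
        if config.pdb_in is not None:
            warnings_list = write_structure_map(config.pdb_in, csp, out / "structure_map.pdb")
            log_lines.extend(f"map: {w}" for w in warnings_list)
    except Exception as exc:
        _write_log(out, log_lines + [f"map: FAILED ({exc})"])
        raise StageError(f"[map] {exc}") from exc

    log_lines.append("status: " + ("converged" if fit.converged else "NOT CONVERGED"))
    _write_log(out, log_lines)
    return out


def _write_log(out_dir: Path, lines: list[str]) -> None:
    (out_dir / "run.log").write_text("\n".join(lines) + "\n")
    for line in lines:
        logger.info(line)
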