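"""Chemical-shift-perturbation table construction and significance selection.

Per residue and titration step the isotope-weighted CSP is

    dd = sqrt( (dH - dH0)^2 + (w_N * (dN - dN0))^2 ),

with the conventional amide ¹⁵N down-weighting w_N = 0.14 by default. The
saturated-step value dd_max normalizes each residue's response, the set of
all dd_max feeds the corrected-standard-deviation cutoff sigma_c, and each
residue's (dH, w_N*dN) trajectory is tested for the straight-line signature
of two-state fast exchange.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, InvalidParameterError
from .peaklist_io import TitrationSeries

DEFAULT_N_WEIGHT = 0.14
DEFAULT_TOL_H = 0.02  # ppm, overlap/link tolerance in 1H
DEFAULT_TOL_N = 0.2   # ppm, overlap/link tolerance in 15N


def compute_csp(delta_H0, delta_N0, delta_H, delta_N, n_weight: float = DEFAULT_N_WEIGHT):
    """Isotope-weighted combined CSP in ppm (vectorized)."""
    if n_weight <= 0:
        raise InvalidParameterError("n_weight must be > 0")
    dH = np.asarray(delta_H, dtype=float) - np.asarray(delta_H0, dtype=float)
    dN = np.asarray(delta_N, dtype=float) - np.asarray(delta_N0, dtype=float)
    out = np.sqrt(dH * dH + (n_weight * dN) ** 2)
    return float(out) if out.ndim == 0 else out


@dataclass
class Trajectory:
    """One residue's peak positions across the series."""

    label: str
    delta_H: np.ndarray
    delta_N: np.ndarray
    intensity: np.ndarray
    overlap: bool = False
    ambiguous: bool = False


def _overlap_flags(series: TitrationSeries, tol_H: float, tol_N: float) -> set[str]:
    """Labels whose peak lies within tolerance of another peak at any step."""
    flagged: set[str] = set()
    for step in series.steps:
        dH = np.array([p.delta_H for p in step.peaks])
        dN = np.array([p.delta_N for p in step.peaks])
        labels = [p.label for p in step.peaks]
        close = (np.abs(dH[:, None] - dH[None, :]) <= tol_H) & (
            np.abs(dN[:, None] - dN[None, :]) <= tol_N
        )
        np.fill_diagonal(close, False)
        for i in np.argwhere(close.any(axis=1)).ravel():
            flagged.add(labels[i])
    return flagged


def track_peaks(
    series: TitrationSeries,
    match_mode: str = "by_label",
    tol_H: float = DEFAULT_TOL_H,
    tol_N: float = DEFAULT_TOL_N,
    n_weight: float = DEFAULT_N_WEIGHT,
) -> dict[str, Trajectory]:
    """Join peaks across steps into per-residue trajectories.

    ``by_label`` matches identical assignment labels; ``nearest`` chains each
    step-k peak to the step-(k+1) peak minimizing the weighted distance
    sqrt(dH^2 + (w_N*dN)^2), rejecting links outside (tol_H, tol_N) and
    flagging (not guessing) ties closer than 1e-6 ppm. Residues whose peak
    sits within tolerance of another peak at any step carry ``overlap=True``.
    """
    if match_mode not in ("by_label", "nearest"):
        raise ValueError(f"unknown match_mode {match_mode!r}")
    overlapped = _overlap_flags(series, tol_H, tol_N)
    n_steps = series.n_steps
    trajectories: dict[str, Trajectory] = {}

    if match_mode == "by_label":
        by_step = [{p.label: p for p in step.peaks} for step in series.steps]
        for label in by_step[0]:
            if not all(label in d for d in by_step):
                warnings.warn(f"label {label!r} missing at some step; dropped", stacklevel=2)
                continue
            ps = [d[label] for d in by_step]
            trajectories[label] = Trajectory(
                label=label,
                delta_H=np.array([p.delta_H for p in ps]),
                delta_N=np.array([p.delta_N for p in ps]),
                intensity=np.array(
                    [np.nan if p.intensity is None else p.intensity for p in ps]
                ),
                overlap=label in overlapped,
            )
        return trajectories

    # nearest-neighbour chaining, seeded by the step-0 assignments
    chains: dict[str, list] = {p.label: [p] for p in series.steps[0].peaks}
    ambiguous: set[str] = set()
    dead: set[str] = set()
    for k in range(1, n_steps):
        nxt = series.steps[k].peaks
        nH = np.array([p.delta_H for p in nxt])
        nN = np.array([p.delta_N for p in nxt])
        for label, chain in chains.items():
            if label in dead:
                continue
            prev = chain[-1]
            dH = nH - prev.delta_H
            dN = nN - prev.delta_N
            dist = np.sqrt(dH**2 + (n_weight * dN) ** 2)
            dist[(np.abs(dH) > tol_H) | (np.abs(dN) > tol_N)] = np.inf
            order = np.argsort(dist)
            if not np.isfinite(dist[order[0]]):
                warnings.warn(f"trajectory {label!r} lost at step {k}", stacklevel=2)
                dead.add(label)
                continue
            if len(order) > 1 and dist[order[1]] - dist[order[0]] < 1e-6:
                ambiguous.add(label)
                dead.add(label)
                continue
            chain.append(nxt[order[0]])
    for label, chain in chains.items():
        if len(chain) != n_steps:
            if label in ambiguous:
                trajectories[label] = Trajectory(
                    label, np.array([]), np.array([]), np.array([]), ambiguous=True
                )
            continue
        trajectories[label] = Trajectory(
            label=label,
            delta_H=np.array([p.delta_H for p in chain]),
            delta_N=np.array([p.delta_N for p in chain]),
            intensity=np.array(
                [np.nan if p.intensity is None else p.intensity for p in chain]
            ),
            overlap=label in overlapped,
        )
    return trajectories


def linearity_check(trajectory: Trajectory, n_weight: float = DEFAULT_N_WEIGHT) -> float:
    """Maximum perpendicular deviation (ppm) from the total-least-squares line
    through the (dH, w_N*dN) trajectory; 0 means perfectly two-state."""
    x = np.asarray(trajectory.delta_H, dtype=float)
    y = n_weight * np.asarray(trajectory.delta_N, dtype=float)
    if x.size < 3:
        raise InsufficientDataError("linearity check needs >= 3 points")
    pts = np.column_stack([x - x.mean(), y - y.mean()])
    # TLS line = first principal direction; deviations = second component
    _, _, vt = np.linalg.svd(pts, full_matrices=False)
    perp = pts @ vt[1]
    return float(np.max(np.abs(perp)))


@dataclass
class SignificanceResult:
    sigma_c: float
    excluded: set = field(default_factory=set)  # indices (or labels) removed by the 3-sigma rule
    iterations: int = 1


def significance_threshold(
    dd_max,
    k_exclude: float = 3.0,
    about_zero: bool = True,
    max_iter: int = 100,
) -> SignificanceResult:
    """Corrected standard deviation sigma_c of a set of dd_max values.

    Iteratively computes the standard deviation of the retained values
    (about zero by default, since CSPs are non-negative with a null near 0),
    removes values exceeding ``k_exclude`` standard deviations, and repeats
    to a fixed point. The final sigma is the significance cutoff: values
    strictly greater than sigma_c are significant.
    """
    v = np.asarray(dd_max, dtype=float)
    if v.size < 3:
        raise InsufficientDataError("need >= 3 dd_max values")
    if np.any(v < 0):
        raise InvalidParameterError("dd_max values must be >= 0")
    retained = np.ones(v.size, dtype=bool)
    iterations = 0
    for _ in range(max_iter):
        iterations += 1
        sub = v[retained]
        if about_zero:
            sigma = float(np.sqrt(np.mean(sub**2)))
            excess = v - 0.0
        else:
            sigma = float(np.std(sub, ddof=1)) if sub.size > 1 else 0.0
            excess = v - float(np.mean(sub))
        new_retained = retained & ~(excess > k_exclude * sigma)
        if new_retained.sum() == 0 or np.array_equal(new_retained, retained):
            retained = new_retained if new_retained.sum() else retained
            break
        retained = new_retained
    excluded = set(np.nonzero(~retained)[0].tolist())
    return SignificanceResult(sigma_c=sigma, excluded=excluded, iterations=iterations)


@dataclass
class CSPTable:
    """Per-residue CSPs across the series plus derived flags.

    ``data`` is indexed by label with one ``dd_step{i}`` column per step,
    then ``dd_max``, ``linearity``, ``overlap``, ``significant``.
    """

    data: pd.DataFrame
    step_columns: list[str]
    step_indices: list[int]
    saturated_step: int           # step index (as labelled in the series)
    saturated_step_position: int  # positional index into the step list
    sigma: SignificanceResult
    saturation_diagnostic: float
    n_weight: float

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="label")


def build_csp_table(
    series: TitrationSeries,
    saturated_step: int | None = None,
    n_weight: float = DEFAULT_N_WEIGHT,
    match_mode: str = "by_label",
    tol_H: float = DEFAULT_TOL_H,
    tol_N: float = DEFAULT_TOL_N,
    sigma_k_exclude: float = 3.0,
    sigma_about_zero: bool = True,
) -> CSPTable:
    """Track peaks, compute per-step CSPs, and select significant residues.

    ``saturated_step`` is the step index whose CSP defines dd_max (the last
    step by default). The saturation diagnostic — max over residues of
    |dd(last) - dd(second last)| — is reported, not enforced.
    """
    traj = track_peaks(series, match_mode=match_mode, tol_H=tol_H, tol_N=tol_N,
                       n_weight=n_weight)
    traj = {k: t for k, t in traj.items() if t.delta_H.size == series.n_steps}
    if not traj:
        raise InsufficientDataError("no complete trajectories")
    step_indices = [s.index for s in series.steps]
    if saturated_step is None:
        saturated_step = step_indices[-1]
    if saturated_step not in step_indices:
        raise InvalidParameterError(f"saturated_step {saturated_step} not in series")
    k_sat = step_indices.index(saturated_step)

    labels = sorted(traj)
    dd = np.zeros((len(labels), series.n_steps))
    lin = np.zeros(len(labels))
    overlap = np.zeros(len(labels), dtype=bool)
    for i, lab in enumerate(labels):
        t = traj[lab]
        dd[i] = compute_csp(t.delta_H[0], t.delta_N[0], t.delta_H, t.delta_N, n_weight)
        lin[i] = linearity_check(t, n_weight) if series.n_steps >= 3 else np.nan
        overlap[i] = t.overlap
    dd_max = dd[:, k_sat]

    sig = significance_threshold(dd_max, k_exclude=sigma_k_exclude,
                                 about_zero=sigma_about_zero)
    significant = dd_max > sig.sigma_c
    sig.excluded = {labels[i] for i in sig.excluded}

    cols = [f"dd_step{idx}" for idx in step_indices]
    data = pd.DataFrame(dd, index=pd.Index(labels, name="label"), columns=cols)
    data["dd_max"] = dd_max
    data["linearity"] = lin
    data["overlap"] = overlap
    data["significant"] = significant

    diagnostic = float(np.max(np.abs(dd[:, -1] - dd[:, -2]))) if series.n_steps >= 2 else np.nan
    return CSPTable(
        data=data,
        step_columns=cols,
        step_indices=step_indices,
        saturated_step=saturated_step,
        saturated_step_position=k_sat,
        sigma=sig,
        saturation_diagnostic=diagnostic,
        n_weight=n_weight,
    )
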