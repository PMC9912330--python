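"""Synthetic titration series with the structure the analysis assumes.

The generator emulates a microfluidic displacement-mixing titration: a
~10 μL on-chip circuit initially holds a protein-only solution (a); each
titration step injects ~2 μL of a protein+ligand solution (b) that carries
the same protein concentration, a saturating molar excess of ligand, and a
TSP internal-standard concentration differing from solution a by at least
one order of magnitude. Injection displaces fully mixed liquid out of the
circuit (single-compartment model), so every solute follows

    c  <-  (c*(V - v) + c_b*v) / V

per step; with constant v the ligand fraction after n steps is the closed
form 1 - (1 - v/V)^n. Protein concentration is identical in both solutions
and therefore constant throughout.

Peak positions follow two-state fast exchange: every residue moves from its
free position toward its saturated position by the bound fraction
f(alpha, beta_D), so noiseless (dH, dN) trajectories are exactly collinear.
The TSP 1D intensity is proportional to the TSP concentration, making it an
affine reporter of the mixing fraction — and hence of alpha — which is what
the calibration inside the global fit assumes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .binding_fit import fractional_shift
from .errors import InvalidParameterError
from .peaklist_io import Peak, TitrationSeries, TitrationStep, write_series

# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class ChipParams:
    """Microfluidic chip and solution parameters.

    Volumes in μL, protein/ligand concentrations in μM, TSP concentrations in
    arbitrary units (only their ratio matters; they must differ by at least
    one order of magnitude so the TSP resonance resolves the mixing ratio).
    """

    circuit_volume: float = 10.0
    injection_volume_mean: float = 2.0
    injection_volume_sd: float = 0.25
    n_steps: int = 10  # number of injections; the series has n_steps + 1 spectra
    protein_conc: float = 1000.0
    ligand_conc_b: float = 5000.0
    tsp_conc_a: float = 0.5
    tsp_conc_b: float = 5.0

    def __post_init__(self):
        if self.circuit_volume <= 0 or self.injection_volume_mean <= 0:
            raise InvalidParameterError("volumes must be > 0")
        if self.injection_volume_mean >= self.circuit_volume:
            raise InvalidParameterError("injection volume must be below the circuit volume")
        if self.injection_volume_sd < 0:
            raise InvalidParameterError("injection_volume_sd must be >= 0")
        if self.n_steps < 1:
            raise InvalidParameterError("n_steps must be >= 1")
        if self.protein_conc <= 0 or self.ligand_conc_b < 0:
            raise InvalidParameterError("concentrations must be positive")
        if self.tsp_conc_a <= 0 or self.tsp_conc_b <= 0:
            raise InvalidParameterError("TSP concentrations must be > 0")
        ratio = self.tsp_conc_b / self.tsp_conc_a
        if not (ratio >= 10.0 or ratio <= 0.1):
            raise InvalidParameterError(
                "TSP concentrations must differ by at least one order of magnitude"
            )

    @property
    def alpha_max(self) -> float:
        return self.ligand_conc_b / self.protein_conc


@dataclass
class NoiseModel:
    """Gaussian observation noise; all zero gives a deterministic series."""

    shift_noise_H: float = 0.002   # ppm sd, order of the <10 Hz 1H resolution at 14.1 T
    shift_noise_N: float = 0.02    # ppm sd
    intensity_rel_noise: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if min(self.shift_noise_H, self.shift_noise_N, self.intensity_rel_noise) < 0:
            raise InvalidParameterError("noise standard deviations must be >= 0")


@dataclass
class ResidueDef:
    label: str
    delta_H_free: float
    delta_N_free: float
    dd_max_H: float = 0.0  # saturated 1H perturbation, ppm (signed); 0 for non-binding
    dd_max_N: float = 0.0


@dataclass
class ProteinDef:
    residues: list[ResidueDef]

    def __post_init__(self):
        labels = [r.label for r in self.residues]
        if len(set(labels)) != len(labels):
            raise InvalidParameterError("residue labels must be unique")


@dataclass
class MixingSchedule:
    """Per-step circuit composition; index 0 is pure solution a."""

    ligand_conc: np.ndarray
    tsp_conc: np.ndarray
    alpha: np.ndarray
    injected_volume: np.ndarray
    protein_conc: float

    @property
    def n_points(self) -> int:
        return self.ligand_conc.size


# ---------------------------------------------------------------------------
# operations


def simulate_mixing_schedule(
    chip: ChipParams,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | None = None,
) -> MixingSchedule:
    """Displacement-mixing recursion over ``chip.n_steps`` injections.

    Injection volumes are Normal(mean, sd) truncated to (0, circuit_volume);
    sd = 0 gives exact volumes. Step 0 is pure solution a (ligand-free).
    """
    if rng is None:
        rng = np.random.default_rng(noise.seed if noise is not None else 0)
    V = chip.circuit_volume
    n = chip.n_steps
    if chip.injection_volume_sd > 0:
        a = (0.0 - chip.injection_volume_mean) / chip.injection_volume_sd
        b = (V - chip.injection_volume_mean) / chip.injection_volume_sd
        vols = stats.truncnorm.rvs(
            a, b, loc=chip.injection_volume_mean, scale=chip.injection_volume_sd,
            size=n, random_state=rng,
        )
    else:
        vols = np.full(n, chip.injection_volume_mean)

    ligand = np.zeros(n + 1)
    tsp = np.zeros(n + 1)
    tsp[0] = chip.tsp_conc_a
    for k in range(1, n + 1):
        v = vols[k - 1]
        ligand[k] = (ligand[k - 1] * (V - v) + chip.ligand_conc_b * v) / V
        tsp[k] = (tsp[k - 1] * (V - v) + chip.tsp_conc_b * v) / V
    return MixingSchedule(
        ligand_conc=ligand,
        tsp_conc=tsp,
        alpha=ligand / chip.protein_conc,
        injected_volume=np.concatenate([[0.0], vols]),
        protein_conc=chip.protein_conc,
    )


def generate_peaklists(
    protein: ProteinDef,
    schedule: MixingSchedule,
    beta_D: float,
    noise: NoiseModel,
    calibration_gain: float = 1.0,
    base_intensity: float = 1.0e6,
    rng: np.random.Generator | None = None,
    metadata: dict | None = None,
) -> TitrationSeries:
    """Two-state fast-exchange peak lists along a mixing schedule.

    At each step every residue sits at delta_free + f(alpha, beta_D)*dd_max
    (componentwise in ¹H and ¹⁵N) plus Gaussian noise; the TSP intensity is
    calibration_gain * tsp_conc * (1 + relative noise).
    """
    if beta_D <= 0:
        raise InvalidParameterError("beta_D must be > 0")
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    f = fractional_shift(schedule.alpha, beta_D)
    steps = []
    for k in range(schedule.n_points):
        peaks = []
        for r in protein.residues:
            dH = r.delta_H_free + f[k] * r.dd_max_H
            dN = r.delta_N_free + f[k] * r.dd_max_N
            if noise.shift_noise_H > 0:
                dH += rng.normal(0.0, noise.shift_noise_H)
            if noise.shift_noise_N > 0:
                dN += rng.normal(0.0, noise.shift_noise_N)
            inten = base_intensity
            if noise.intensity_rel_noise > 0:
                inten *= 1.0 + rng.normal(0.0, noise.intensity_rel_noise)
            peaks.append(Peak(label=r.label, delta_H=dH, delta_N=dN, intensity=inten))
        i_tsp = calibration_gain * schedule.tsp_conc[k]
        if noise.intensity_rel_noise > 0:
            i_tsp *= 1.0 + rng.normal(0.0, noise.intensity_rel_noise)
        steps.append(TitrationStep(index=k, peaks=peaks, i_tsp=i_tsp))
    return TitrationSeries(steps=steps, metadata=metadata or {"source": "synthetic"})


# ---------------------------------------------------------------------------
# packaged hFynSH3-mimic fixture

# Binding patches on the SH3 backbone (RT/n-Src loop faces and the 3-10 helix
# region): exactly the residues expected to respond to the peptide.
HFYN_PATCHES = (
    (96, 100),
    (117, 120),
    (135, 137),
)
#: residue positions dropped from the span 84..147 (prolines / unassigned amides)
_UNASSIGNED = {85, 94, 104, 123, 133}
#: identities fixed by the system being mimicked; filler elsewhere
_NAMED = {
    96: "Arg", 98: "Glu", 100: "Asp", 117: "Gly", 119: "Trp", 120: "Trp",
    132: "Tyr", 135: "Tyr", 136: "Asn", 137: "Tyr",
}
_FILLER = ("Ala", "Ser", "Leu", "Gly", "Thr", "Val", "Lys", "Glu", "Asp",
           "Ile", "Phe", "Asn", "Gln", "Arg", "His", "Met")


def hfyn_residue_numbers() -> list[int]:
    """The 59 assigned backbone-amide positions of the mimic."""
    return [n for n in range(84, 148) if n not in _UNASSIGNED]


def perturbed_residue_numbers() -> list[int]:
    return [n for lo, hi in HFYN_PATCHES for n in range(lo, hi + 1)]


def make_protein_hfyn(rng: np.random.Generator) -> ProteinDef:
    """59-amide hFynSH3 mimic: elevated dd_max exactly on the three patches.

    Free peaks are placed uniformly in a typical amide window (7.5-9.5 ppm ¹H,
    105-130 ppm ¹⁵N) with a minimum separation of twice the default overlap
    tolerance, so the fixture is overlap-free by construction. Perturbed
    residues draw |dd_max| from a narrow band (0.20-0.26 ppm ¹H,
    0.9-1.1 ppm ¹⁵N, random sign); non-binding residues have dd_max = 0.
    """
    numbers = hfyn_residue_numbers()
    perturbed = set(perturbed_residue_numbers())
    placed_H: list[float] = []
    placed_N: list[float] = []
    residues = []
    for i, num in enumerate(numbers):
        name = _NAMED.get(num, _FILLER[i % len(_FILLER)])
        # rejection-sample free positions: at least 2x the overlap tolerance apart
        while True:
            h = rng.uniform(7.5, 9.5)
            nn = rng.uniform(105.0, 130.0)
            clash = any(
                abs(h - ph) < 0.04 and abs(nn - pn) < 0.4
                for ph, pn in zip(placed_H, placed_N)
            )
            if not clash:
                break
        placed_H.append(h)
        placed_N.append(nn)
        if num in perturbed:
            ddH = rng.uniform(0.20, 0.26) * rng.choice([-1.0, 1.0])
            ddN = rng.uniform(0.9, 1.1) * rng.choice([-1.0, 1.0])
        else:
            ddH = ddN = 0.0
        residues.append(ResidueDef(f"{name}{num}", h, nn, ddH, ddN))
    return ProteinDef(residues=residues)


def make_fixture_hfyn(
    seed: int = 0,
    k_d: float = 48.0,
    protein_conc: float = 1000.0,
    chip: ChipParams | None = None,
    noise: NoiseModel | None = None,
    noiseless: bool = False,
    calibration_gain: float = 1.0,
) -> tuple[TitrationSeries, dict]:
    """Packaged 11-experiment titration fixture plus its ground truth.

    Defaults: K_D = 48 μM, [P] = 1000 μM (so beta_D = 0.048), alpha_max = 5,
    10 injections of 2 ± 0.25 μL into a 10 μL circuit, default observation
    noise. ``noiseless=True`` zeroes all noise sources including the
    injection-volume jitter.
    """
    if chip is None:
        chip = ChipParams(protein_conc=protein_conc,
                          ligand_conc_b=5.0 * protein_conc,
                          injection_volume_sd=0.0 if noiseless else 0.25)
    if noise is None:
        noise = (NoiseModel(0.0, 0.0, 0.0, seed=seed) if noiseless
                 else NoiseModel(seed=seed))
    rng = np.random.default_rng(seed)
    protein = make_protein_hfyn(rng)
    schedule = simulate_mixing_schedule(chip, noise, rng=rng)
    beta_D = k_d / chip.protein_conc
    series = generate_peaklists(
        protein, schedule, beta_D, noise, calibration_gain=calibration_gain,
        rng=rng,
        metadata={
            "source": "synthetic hFynSH3 mimic",
            "alpha_max": chip.alpha_max,
            "protein_conc": chip.protein_conc,
            "seed": seed,
        },
    )
    # true TSP->alpha calibration: alpha = slope*I + intercept with I = gain*tsp
    slope_true = chip.alpha_max / (calibration_gain * (chip.tsp_conc_b - chip.tsp_conc_a))
    intercept_true = -slope_true * calibration_gain * chip.tsp_conc_a
    ground_truth = {
        "K_D": k_d,
        "beta_D": beta_D,
        "protein_conc": chip.protein_conc,
        "alpha_max": chip.alpha_max,
        "alpha": schedule.alpha.tolist(),
        "ligand_conc": schedule.ligand_conc.tolist(),
        "injected_volume": schedule.injected_volume.tolist(),
        "cal_slope": slope_true,
        "cal_intercept": intercept_true,
        "perturbed_residues": perturbed_residue_numbers(),
        "perturbed_labels": [
            r.label for r in protein.residues if r.dd_max_H != 0.0 or r.dd_max_N != 0.0
        ],
        "dd_max_true": {
            r.label: float(np.hypot(r.dd_max_H, 0.14 * r.dd_max_N))
            for r in protein.residues
        },
        "n_labels": len(protein.residues),
        "noise": asdict(noise),
        "chip": asdict(chip),
    }
    return series, ground_truth


def write_fixture(series: TitrationSeries, ground_truth: dict, out_dir: str | Path,
                  manifest_format: str = "csv", peaklist_dialect: str = "csv") -> Path:
    """Write the series plus a ground-truth sidecar; returns the manifest path."""
    out_dir = Path(out_dir)
    manifest = write_series(series, out_dir, manifest_format=manifest_format,
                            peaklist_dialect=peaklist_dialect)
    (out_dir / "ground_truth.json").write_text(json.dumps(ground_truth, indent=1))
    return manifest
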