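"""Peak-list and titration-series I/O.

Two peak-list dialects are supported:

* ``sparky`` — whitespace-separated ``Assignment  w1  w2  [Data Height]``
  text lists. For a ¹H–¹⁵N HSQC the conventional axis order is w1 = ¹⁵N,
  w2 = ¹H; this is the default and can be overridden. The assignment is
  taken as everything left of the trailing numeric columns, so labels that
  contain spaces (side-chain tags such as ``Trp119 NHe``) survive a
  round trip; a label that is itself a bare number is indistinguishable
  from a data column and is only supported by the CSV dialect.
* ``csv`` — self-describing, header ``label,delta_H_ppm,delta_N_ppm,intensity``.

A titration series is a manifest (CSV with columns ``step,peaklist_path,I_TSP``
or an equivalent YAML document) pointing at one peak-list file per step. The
internal-standard (TSP) intensity comes from the separate 1D spectra, hence it
lives in the manifest rather than in the 2D peak lists. Step 0 is the
protein-only reference spectrum and must be present.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import (
    DuplicateLabelError,
    ManifestError,
    PeaklistParseError,
)

SPARKY_DIALECT = "sparky"
CSV_DIALECT = "csv"
_CSV_HEADER = ["label", "delta_H_ppm", "delta_N_ppm", "intensity"]


@dataclass(frozen=True)
class Peak:
    """One assigned resonance: label, ¹H and ¹⁵N shifts (ppm), optional intensity."""

    label: str
    delta_H: float
    delta_N: float
    intensity: float | None = None

    def __post_init__(self):
        if not self.label or not self.label.strip():
            raise ValueError("peak label must be non-empty")
        if not (math.isfinite(self.delta_H) and math.isfinite(self.delta_N)):
            raise ValueError(f"non-finite chemical shift for {self.label!r}")


@dataclass
class TitrationStep:
    index: int
    peaks: list[Peak]
    i_tsp: float

    def __post_init__(self):
        if self.i_tsp is None or not math.isfinite(self.i_tsp):
            raise ManifestError(f"step {self.index}: missing or non-finite I_TSP")


@dataclass
class TitrationSeries:
    """Ordered titration steps; step 0 is the protein-only reference."""

    steps: list[TitrationStep]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        idx = [s.index for s in self.steps]
        if sorted(idx) != idx or len(set(idx)) != len(idx):
            self.steps = sorted(self.steps, key=lambda s: s.index)
            idx = [s.index for s in self.steps]
        if len(set(idx)) != len(idx):
            raise ManifestError(f"duplicate step indices: {idx}")
        if not self.steps or self.steps[0].index != 0:
            raise ManifestError("series must contain step 0 (free-protein reference)")

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    @property
    def i_tsp(self) -> list[float]:
        return [s.i_tsp for s in self.steps]


def _parse_float(token: str, lineno: int, what: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise PeaklistParseError(f"non-numeric {what}: {token!r}", lineno) from None


def _is_float(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_peaklist(
    path: str | Path,
    dialect: str = SPARKY_DIALECT,
    axis_order: tuple[str, str] = ("N", "H"),
) -> list[Peak]:
    """Read one peak list.

    ``axis_order`` names the nuclei of (w1, w2) for the Sparky dialect;
    the HSQC convention ``("N", "H")`` is the default.
    """
    path = Path(path)
    if dialect == CSV_DIALECT:
        return _read_csv(path)
    if dialect != SPARKY_DIALECT:
        raise ValueError(f"unknown peak-list dialect {dialect!r}")
    if set(axis_order) != {"H", "N"}:
        raise ValueError(f"axis_order must name H and N, got {axis_order!r}")

    peaks: list[Peak] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.split()[0].lower() == "assignment":
                continue  # header row
            tokens = line.split()
            # trailing numeric columns: w1 w2 [height]
            n_numeric = 0
            for tok in reversed(tokens):
                if _is_float(tok) and n_numeric < 3:
                    n_numeric += 1
                else:
                    break
            if n_numeric < 2:
                raise PeaklistParseError(
                    f"expected at least two numeric shift columns in {line!r}", lineno
                )
            label = " ".join(tokens[: len(tokens) - n_numeric])
            if not label:
                raise PeaklistParseError(f"missing assignment label in {line!r}", lineno)
            nums = [
                _parse_float(t, lineno, "shift/intensity")
                for t in tokens[len(tokens) - n_numeric :]
            ]
            w1, w2 = nums[0], nums[1]
            height = nums[2] if n_numeric == 3 else None
            shifts = dict(zip(axis_order, (w1, w2)))
            if label in seen:
                raise DuplicateLabelError(f"duplicate label {label!r} at line {lineno}")
            seen.add(label)
            peaks.append(
                Peak(label=label, delta_H=shifts["H"], delta_N=shifts["N"], intensity=height)
            )
    return peaks


def _read_csv(path: Path) -> list[Peak]:
    peaks: list[Peak] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return []
        missing = {"label", "delta_H_ppm", "delta_N_ppm"} - set(reader.fieldnames)
        if missing:
            raise PeaklistParseError(f"CSV header missing columns {sorted(missing)}", 1)
        for row in reader:
            lineno = reader.line_num
            label = (row.get("label") or "").strip()
            if not label:
                raise PeaklistParseError("missing label", lineno)
            if label in seen:
                raise DuplicateLabelError(f"duplicate label {label!r} at line {lineno}")
            seen.add(label)
            dH = _parse_float(row["delta_H_ppm"], lineno, "delta_H_ppm")
            dN = _parse_float(row["delta_N_ppm"], lineno, "delta_N_ppm")
            raw_i = (row.get("intensity") or "").strip()
            inten = _parse_float(raw_i, lineno, "intensity") if raw_i else None
            peaks.append(Peak(label, dH, dN, inten))
    return peaks


def write_peaklist(
    peaks: list[Peak],
    path: str | Path,
    dialect: str = SPARKY_DIALECT,
    axis_order: tuple[str, str] = ("N", "H"),
) -> Path:
    """Write a peak list; round-trips through :func:`read_peaklist` to 1e-5 ppm."""
    path = Path(path)
    if dialect == CSV_DIALECT:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(_CSV_HEADER)
            for p in peaks:
                writer.writerow(
                    [
                        p.label,
                        f"{p.delta_H:.5f}",
                        f"{p.delta_N:.5f}",
                        "" if p.intensity is None else f"{p.intensity:.6g}",
                    ]
                )
        return path
    if dialect != SPARKY_DIALECT:
        raise ValueError(f"unknown peak-list dialect {dialect!r}")

    with_height = any(p.intensity is not None for p in peaks)
    width = max([len(p.label) for p in peaks], default=10) + 2
    with open(path, "w") as fh:
        header = f"{'Assignment':>{width}} {'w1':>10} {'w2':>10}"
        if with_height:
            header += f" {'Data Height':>13}"
        fh.write(header + "\n\n")
        for p in peaks:
            shifts = {"H": p.delta_H, "N": p.delta_N}
            row = f"{p.label:>{width}} {shifts[axis_order[0]]:>10.5f} {shifts[axis_order[1]]:>10.5f}"
            if with_height:
                row += f" {0.0 if p.intensity is None else p.intensity:>13.6g}"
            fh.write(row + "\n")
    return path


def _peaklist_dialect_for(path: Path) -> str:
    return CSV_DIALECT if path.suffix.lower() == ".csv" else SPARKY_DIALECT


def read_series(manifest_path: str | Path) -> TitrationSeries:
    """Load a titration series from a CSV or YAML manifest.

    Steps are sorted by index; a manifest without step 0 or with a missing
    ``I_TSP`` raises :class:`ManifestError`.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(manifest_path)
    base = manifest_path.parent
    rows: list[dict]
    metadata: dict = {}
    if manifest_path.suffix.lower() in (".yaml", ".yml"):
        doc = yaml.safe_load(manifest_path.read_text())
        if not isinstance(doc, dict) or "steps" not in doc:
            raise ManifestError("YAML manifest must be a mapping with a 'steps' list")
        metadata = doc.get("metadata") or {}
        rows = [
            {
                "step": entry.get("step"),
                "peaklist_path": entry.get("peaklist_path") or entry.get("peaklist"),
                "I_TSP": entry.get("I_TSP", entry.get("i_tsp")),
            }
            for entry in doc["steps"]
        ]
    else:
        with open(manifest_path, newline="") as fh:
            reader = csv.DictReader(fh)
            required = {"step", "peaklist_path", "I_TSP"}
            if reader.fieldnames is None or required - set(reader.fieldnames):
                raise ManifestError(
                    f"manifest header must contain {sorted(required)}, got {reader.fieldnames}"
                )
            rows = list(reader)

    steps = []
    for row in rows:
        try:
            idx = int(row["step"])
        except (TypeError, ValueError):
            raise ManifestError(f"bad step index {row.get('step')!r}") from None
        raw_tsp = row.get("I_TSP")
        if raw_tsp is None or (isinstance(raw_tsp, str) and not raw_tsp.strip()):
            raise ManifestError(f"step {idx}: missing I_TSP")
        try:
            i_tsp = float(raw_tsp)
        except (TypeError, ValueError):
            raise ManifestError(f"step {idx}: non-numeric I_TSP {raw_tsp!r}") from None
        rel = row.get("peaklist_path")
        if not rel:
            raise ManifestError(f"step {idx}: missing peaklist_path")
        plist = Path(rel)
        if not plist.is_absolute():
            plist = base / plist
        if not plist.exists():
            raise FileNotFoundError(plist)
        peaks = read_peaklist(plist, dialect=_peaklist_dialect_for(plist))
        steps.append(TitrationStep(index=idx, peaks=peaks, i_tsp=i_tsp))
    steps.sort(key=lambda s: s.index)
    return TitrationSeries(steps=steps, metadata=metadata)


def write_series(
    series: TitrationSeries,
    out_dir: str | Path,
    manifest_format: str = "csv",
    peaklist_dialect: str = CSV_DIALECT,
) -> Path:
    """Write one peak-list file per step plus a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = ".csv" if peaklist_dialect == CSV_DIALECT else ".list"
    names = []
    for step in series.steps:
        name = f"step{step.index:02d}{ext}"
        write_peaklist(step.peaks, out_dir / name, dialect=peaklist_dialect)
        names.append(name)

    if manifest_format == "csv":
        manifest = out_dir / "manifest.csv"
        with open(manifest, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["step", "peaklist_path", "I_TSP"])
            for step, name in zip(series.steps, names):
                writer.writerow([step.index, name, f"{step.i_tsp:.10g}"])
    elif manifest_format in ("yaml", "yml"):
        manifest = out_dir / "manifest.yaml"
        doc = {
            "metadata": series.metadata,
            "steps": [
                {"step": step.index, "peaklist_path": name, "I_TSP": float(step.i_tsp)}
                for step, name in zip(series.steps, names)
            ],
        }
        manifest.write_text(yaml.safe_dump(doc, sort_keys=False))
    else:
        raise ValueError(f"unknown manifest format {manifest_format!r}")
    return manifest
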