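"""Binding-site mapping: sequence patches and structure coloring.

Significant residues are grouped into contiguous sequence patches; a
user-supplied PDB file can be re-written with each residue's saturated CSP
(dd_max, ppm x 100) in the temperature-factor column so any molecular viewer
can color the binding site.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .errors import PDBFormatError

_LABEL_RE = re.compile(r"^\s*([A-Za-z]{0,3})\s*(\d+)\s*(.*?)\s*$")


def parse_label(label: str) -> tuple[int, str] | None:
    """Residue number and (possibly empty) side-chain tag from a label.

    ``'Trp119 NHe'`` -> (119, 'NHe'); ``'Arg96'`` -> (96, ''); returns None
    when no residue number can be found.
    """
    m = _LABEL_RE.match(label)
    if not m or not m.group(2):
        return None
    return int(m.group(2)), m.group(3)


@dataclass
class Patch:
    start: int
    end: int
    members: list[str]


@dataclass
class PatchReport:
    patches: list[Patch]
    singletons: list[str] = field(default_factory=list)
    side_chain_hits: list[str] = field(default_factory=list)
    unparsed: list[str] = field(default_factory=list)


def find_patches(csp, max_gap: int = 1) -> PatchReport:
    """Group significant backbone residues into sequence patches.

    Consecutive significant residues no more than ``max_gap`` apart in
    sequence form one patch; runs of a single residue are reported as
    singletons. Side-chain signals (non-empty tag after the residue number)
    are listed separately but attributed to their residue number. Labels
    without a parseable residue number go to the singleton bucket with a
    warning. Deterministic and independent of input order.
    """
    significant = csp.data.index[csp.data["significant"]].tolist()
    backbone: dict[int, list[str]] = {}
    report = PatchReport(patches=[])
    for label in significant:
        parsed = parse_label(label)
        if parsed is None:
            warnings.warn(f"cannot parse residue number from {label!r}", stacklevel=2)
            report.unparsed.append(label)
            report.singletons.append(label)
            continue
        num, tag = parsed
        if tag:
            report.side_chain_hits.append(label)
        else:
            backbone.setdefault(num, []).append(label)
    numbers = sorted(backbone)
    run: list[int] = []
    for num in numbers:
        if run and num - run[-1] > max_gap:
            _close_run(run, backbone, report)
            run = []
        run.append(num)
    if run:
        _close_run(run, backbone, report)
    return report


def _close_run(run, backbone, report):
    members = [lab for n in run for lab in sorted(backbone[n])]
    if len(run) >= 2:
        report.patches.append(Patch(start=run[0], end=run[-1], members=members))
    else:
        report.singletons.extend(members)


def patch_report_dict(report: PatchReport) -> dict:
    return {
        "patches": [
            {"start": p.start, "end": p.end, "members": p.members} for p in report.patches
        ],
        "singletons": report.singletons,
        "side_chain_hits": report.side_chain_hits,
        "unparsed": report.unparsed,
    }


def write_structure_map(
    pdb_in: str | Path,
    csp,
    pdb_out: str | Path,
    scale: float = 100.0,
    sentinel: float = -1.0,
    combine: str = "max",
) -> list[str]:
    """Copy a PDB with dd_max (ppm x ``scale``) in the temperature-factor column.

    Residues absent from the CSP table get the ``sentinel`` value; values are
    clamped to [0, 999.99] to fit the fixed-width field. When a residue has
    both a backbone and a side-chain entry the ``combine`` rule ('max' or
    'backbone') decides which dd_max is written. Only the B-factor bytes of
    ATOM/HETATM records change. Returns the residue numbers in the table
    that were never seen in the structure (as warning strings).
    """
    if combine not in ("max", "backbone"):
        raise ValueError(f"unknown combine rule {combine!r}")
    by_resnum: dict[int, float] = {}
    for label, row in csp.data.iterrows():
        parsed = parse_label(label)
        if parsed is None:
            continue
        num, tag = parsed
        val = float(row["dd_max"])
        if combine == "backbone" and tag and num in by_resnum:
            continue
        if combine == "backbone" and not tag:
            by_resnum[num] = val
        else:
            by_resnum[num] = max(by_resnum.get(num, -float("inf")), val)

    seen: set[int] = set()
    out_lines: list[str] = []
    with open(pdb_in, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            record = line[:6]
            if record in ("ATOM  ", "HETATM"):
                body = line.rstrip("\r\n")
                if len(body) < 66:
                    raise PDBFormatError(
                        f"ATOM/HETATM record shorter than 66 columns: {body!r}", lineno
                    )
                try:
                    resnum = int(body[22:26])
                except ValueError:
                    raise PDBFormatError(
                        f"unreadable residue number field {body[22:26]!r}", lineno
                    ) from None
                if resnum in by_resnum:
                    seen.add(resnum)
                    b = min(max(by_resnum[resnum] * scale, 0.0), 999.99)
                else:
                    b = sentinel
                newline = line[len(body):]
                out_lines.append(body[:60] + f"{b:6.2f}" + body[66:] + newline)
            else:
                out_lines.append(line)
    missing = sorted(set(by_resnum) - seen)
    warning_list = [f"residue {n} in CSP table absent from structure" for n in missing]
    for w in warning_list:
        warnings.warn(w, stacklevel=2)
    Path(pdb_out).write_text("".join(out_lines))
    return warning_list
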