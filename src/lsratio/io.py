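"""Reading and writing spectra: per-spectrum CSV, JSON dataset manifests, JCAMP-DX.

CSV is the canonical on-disk format (two columns, full float precision).
JCAMP-DX is supported read-only in AFFN encoding, which covers spectra
exported from FTIR instrument software; DIFDUP-compressed files are out of
scope.  A dataset on disk is a directory of CSV files plus a JSON manifest
carrying the per-measurement metadata.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import FormatError
from .synthetic import GeneratorConfig, Spectrum

__all__ = [
    "write_spectrum_csv",
    "read_spectrum_csv",
    "read_jcampdx",
    "save_dataset",
    "load_dataset",
]

CSV_HEADER = "wavenumber_cm-1,absorbance_au"
MANIFEST_NAME = "manifest.json"


def write_spectrum_csv(spectrum: Spectrum, path: str | Path) -> Path:
    """Write a spectrum as a two-column CSV in increasing wavenumber order.

    Values are written with shortest-exact ``repr`` so a read round-trips the
    floats bitwise.
    """
    path = Path(path)
    lines = [CSV_HEADER]
    lines.extend(
        f"{nu!r},{a!r}"
        for nu, a in zip(spectrum.wavenumbers.tolist(), spectrum.absorbances.tolist())
    )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_spectrum_csv(path: str | Path, **metadata) -> Spectrum:
    """Read a two-column spectrum CSV; metadata fields may be supplied."""
    path = Path(path)
    text = path.read_text().strip().splitlines()
    if not text or not text[0].strip().startswith("wavenumber"):
        raise FormatError(f"{path}: missing '{CSV_HEADER}' header")
    nus, absorb = [], []
    for i, line in enumerate(text[1:], start=2):
        parts = line.split(",")
        if len(parts) != 2:
            raise FormatError(f"{path}:{i}: expected two comma-separated values")
        nus.append(float(parts[0]))
        absorb.append(float(parts[1]))
    return Spectrum(wavenumbers=np.array(nus), absorbances=np.array(absorb), **metadata)


# ---------------------------------------------------------------------------
# JCAMP-DX (AFFN only)
# ---------------------------------------------------------------------------

_LDR = re.compile(r"^##\s*([^=]+?)\s*=\s*(.*)$")
# AFFN numbers may be separated by whitespace, commas or semicolons; '+'/'-'
# signs also act as separators in tabular lines.
_AFFN_NUM = re.compile(r"[+-]?\d+\.?\d*(?:[eE][+-]?\d+)?")


def _parse_ldrs(text: str) -> tuple[dict[str, str], dict[str, list[str]]]:
    """Split a JCAMP file into labelled data records; data blocks keep their lines."""
    labels: dict[str, str] = {}
    blocks: dict[str, list[str]] = {}
    current_block: list[str] | None = None
    for raw in text.splitlines():
        line = raw.split("$$")[0].rstrip()  # strip comments
        if not line:
            continue
        m = _LDR.match(line)
        if m:
            name = m.group(1).replace(" ", "").replace("-", "").replace("_", "").upper()
            value = m.group(2).strip()
            labels[name] = value
            if name in ("XYDATA", "XYPOINTS"):
                current_block = []
                blocks[name] = current_block
            else:
                current_block = None
        elif current_block is not None:
            current_block.append(line)
    return labels, blocks


def _require(labels: dict[str, str], name: str, path: Path) -> str:
    if name not in labels:
        raise FormatError(f"{path}: missing required JCAMP label ##{name}")
    return labels[name]


def read_jcampdx(path: str | Path, **metadata) -> Spectrum:
    """Read an AFFN-encoded JCAMP-DX spectrum.

    Supports ``##XYDATA=(X++(Y..Y))`` (one leading abscissa per line followed
    by ordinates at uniform spacing) and ``##XYPOINTS=(XY..XY)`` pairs.
    XFACTOR/YFACTOR are applied; a descending file grid (FIRSTX > LASTX) is
    returned ascending.
    """
    path = Path(path)
    labels, blocks = _parse_ldrs(path.read_text())

    xfactor = float(_require(labels, "XFACTOR", path))
    yfactor = float(_require(labels, "YFACTOR", path))
    firstx = float(_require(labels, "FIRSTX", path))
    lastx = float(_require(labels, "LASTX", path))
    npoints = int(float(_require(labels, "NPOINTS", path)))

    if "XYDATA" in blocks:
        if npoints > 1:
            dx = (lastx - firstx) / (npoints - 1)
        else:
            dx = 0.0
        xs: list[float] = []
        ys: list[float] = []
        for line in blocks["XYDATA"]:
            nums = [float(tok) for tok in _AFFN_NUM.findall(line)]
            if not nums:
                continue
            x0 = nums[0] * xfactor
            for j, y in enumerate(nums[1:]):
                xs.append(x0 + j * dx)
                ys.append(y * yfactor)
    elif "XYPOINTS" in blocks:
        xs, ys = [], []
        for line in blocks["XYPOINTS"]:
            nums = [float(tok) for tok in _AFFN_NUM.findall(line)]
            if len(nums) % 2:
                raise FormatError(f"{path}: odd value count in XYPOINTS line {line!r}")
            xs.extend(v * xfactor for v in nums[0::2])
            ys.extend(v * yfactor for v in nums[1::2])
    else:
        raise FormatError(f"{path}: missing required JCAMP label ##XYDATA or ##XYPOINTS")

    if len(ys) != npoints:
        raise FormatError(
            f"{path}: NPOINTS={npoints} but decoded {len(ys)} ordinate values"
        )

    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if firstx > lastx:
        x, y = x[::-1], y[::-1]
    return Spectrum(wavenumbers=x, absorbances=y, **metadata)


# ---------------------------------------------------------------------------
# Dataset manifests
# ---------------------------------------------------------------------------

def _grid_description(spectrum: Spectrum) -> dict:
    nu = spectrum.wavenumbers
    step = float(nu[1] - nu[0]) if nu.size > 1 else 0.0
    uniform = nu.size > 1 and bool(np.allclose(np.diff(nu), step))
    return {
        "min": float(nu[0]),
        "max": float(nu[-1]),
        "step": step if uniform else None,
        "n_points": int(nu.size),
    }


def save_dataset(
    spectra: Sequence[Spectrum],
    out_dir: str | Path,
    provenance: str | GeneratorConfig = "external",
) -> Path:
    """Write one CSV per spectrum plus a JSON manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(provenance, GeneratorConfig):
        provenance = "generator:" + json.dumps(
            {k: getattr(provenance, k) for k in provenance.__dataclass_fields__},
            sort_keys=True,
            default=list,
        )
    entries = []
    for i, sp in enumerate(spectra):
        fname = f"spectrum{i:04d}.csv"
        write_spectrum_csv(sp, out_dir / fname)
        entries.append(
            {
                "file": fname,
                "session_id": sp.session_id,
                "sample_id": sp.sample_id,
                "replicate": sp.replicate,
                "true_dppc": sp.true_dppc,
                "true_sm": sp.true_sm,
                "water_vapor": sp.water_vapor,
            }
        )
    manifest = {
        "grid": _grid_description(spectra[0]) if spectra else None,
        "provenance": provenance,
        "entries": entries,
    }
    manifest_path = out_dir / MANIFEST_NAME
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest_path


def load_dataset(manifest_path: str | Path) -> list[Spectrum]:
    """Load all spectra listed in a manifest, metadata attached, manifest order."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    declared = manifest.get("grid")
    spectra: list[Spectrum] = []
    for entry in manifest["entries"]:
        fpath = base / entry["file"]
        if not fpath.exists():
            raise FormatError(f"manifest entry {entry['file']!r}: file not found")
        sp = read_spectrum_csv(
            fpath,
            session_id=entry.get("session_id", ""),
            sample_id=entry.get("sample_id", ""),
            replicate=entry.get("replicate", 0),
            true_dppc=entry.get("true_dppc"),
            true_sm=entry.get("true_sm"),
            water_vapor=entry.get("water_vapor", False),
        )
        if declared is not None:
            nu = sp.wavenumbers
            if (
                nu.size != declared["n_points"]
                or abs(nu[0] - declared["min"]) > 1e-9
                or abs(nu[-1] - declared["max"]) > 1e-9
            ):
                raise FormatError(
                    f"manifest entry {entry['file']!r}: grid does not match "
                    f"the declared dataset grid"
                )
        spectra.append(sp)
    return spectra
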