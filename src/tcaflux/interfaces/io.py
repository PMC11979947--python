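"""Tabular result writers and fixture readers.

Result files are TSV with ``# key: value`` metadata header lines (tissue,
seed, tolerances, provenance hash) so any published file can be regenerated
from its embedded configuration.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from ..model_assembly import ReactionNetwork
from ..steady_state import SteadyStateResult

__all__ = [
    "provenance_hash",
    "write_steady_state",
    "write_table",
    "read_table",
    "read_fixture",
    "FixtureError",
]


class FixtureError(ValueError):
    pass


def provenance_hash(net: ReactionNetwork) -> str:
    payload = json.dumps(net.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _write_with_metadata(frame: pd.DataFrame, path: Path,
                         metadata: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for key, value in metadata.items():
            fh.write(f"# {key}: {value}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def write_table(frame: pd.DataFrame, path: Path,
                metadata: dict | None = None) -> None:
    _write_with_metadata(frame, path, metadata or {})


def read_table(path: Path) -> tuple[pd.DataFrame, dict]:
    """Read a result/fixture TSV, returning the frame and its metadata."""
    path = Path(path)
    metadata: dict[str, str] = {}
    with path.open() as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("# ") and ": " in line:
            key, _, value = line[2:].strip().partition(": ")
            metadata[key] = value
            body_start = i + 1
        else:
            break
    from io import StringIO
    frame = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t")
    return frame, metadata


def write_steady_state(result: SteadyStateResult, net: ReactionNetwork,
                       out_dir: Path, seed: int | None = None) -> None:
    out_dir = Path(out_dir)
    meta = {
        "tissue": net.tissue,
        "seed": seed,
        "converged": result.converged,
        "residual_norm": result.residual_norm,
        "moiety_drift": result.moiety_drift,
        "provenance_hash": provenance_hash(net),
    }
    conc = pd.DataFrame(sorted(result.concentrations.items()),
                        columns=["species", "concentration_mM"])
    flux = pd.DataFrame(
        [(k, v) for k, v in result.fluxes.items()],
        columns=["reaction", "flux_nmol_min_mg"])
    write_table(conc, out_dir / f"{net.tissue}_concentrations.tsv", meta)
    write_table(flux, out_dir / f"{net.tissue}_fluxes.tsv", meta)


def read_fixture(path: Path) -> pd.DataFrame:
    """Read a parameter fixture CSV with per-line error reporting."""
    path = Path(path)
    rows = []
    header: list[str] | None = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",")
            if header is None:
                header = parts
                continue
            if len(parts) != len(header):
                raise FixtureError(
                    f"{path}:{lineno}: expected {len(header)} fields, "
                    f"got {len(parts)}")
            row = dict(zip(header, parts))
            if "value" in row:
                try:
                    row["value"] = float(row["value"])
                except ValueError as exc:
                    raise FixtureError(
                        f"{path}:{lineno}: bad value {row['value']!r}"
                    ) from exc
            rows.append(row)
    if header is None:
        raise FixtureError(f"{path}: empty fixture")
    return pd.DataFrame(rows, columns=header)
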