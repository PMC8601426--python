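"""Readers, writers and the synthetic-fixture generator.

Plain-text formats throughout: 4-column TSV pairs records, UCSC-style
chrom.sizes, XYZ and pseudo-atom PDB structures, 2-column contact-map TSV
with an ``# n_beads`` header, whitespace-delimited dense distance maps
with NaN for missing entries.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from datetime import datetime, timezone
from pathlib import Path
from string import ascii_uppercase, ascii_lowercase, digits
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .conformations import Conformation
from .contacts import ContactMap

__all__ = [
    "load_params_config",
    "write_trajectory_frame",
    "read_pairs",
    "read_chrom_sizes",
    "write_structure",
    "read_xyz",
    "write_contact_map",
    "read_contact_map",
    "write_distance_map",
    "read_distance_map",
    "make_fixture",
    "Provenance",
]

logger = logging.getLogger(__name__)

#: PDB coordinates are DPD lengths times this factor (documented in REMARK).
PDB_SCALE = 10.0

_CHAIN_IDS = ascii_uppercase + ascii_lowercase + digits


@dataclass
class Provenance:
    """What produced an artifact: tool version, config, seeds, digests."""

    tool: str
    version: str
    config: dict
    seeds: dict
    input_digests: dict
    timestamp: str = ""

    def __post_init__(self):
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def load_params_config(path: str | Path):
    """Read a flat ``key = value`` config file into simulation settings.

    Keys matching :class:`~chromdpd.params.DPDParams` fields build the
    parameter set; any remaining keys (e.g. ``n_steps``, ``seed``) are
    returned as a dict of extras. '#' starts a comment.
    """
    from .params import DPDParams

    raw: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"config line without '=': {line!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        raw[key] = value
    fields = {f.name: f.type for f in
              __import__("dataclasses").fields(DPDParams)}
    kwargs = {}
    extras = {}
    for key, value in raw.items():
        if key in fields:
            kwargs[key] = value if key == "theta" else float(value)
        else:
            extras[key] = int(value) if value.lstrip("-").isdigit() \
                else float(value)
    return DPDParams(**kwargs), extras


def write_trajectory_frame(
    fh,
    positions: np.ndarray,
    species: np.ndarray,
    include_solvent: bool = False,
    comment: str = "",
) -> None:
    """Append one XYZ frame (element P = polymer, S = solvent).

    Solvent beads are suppressed by default — trajectories of large
    solvated systems are dominated by solvent otherwise.
    """
    keep = np.ones(len(positions), dtype=bool) if include_solvent \
        else (np.asarray(species) == 0)
    fh.write(f"{int(keep.sum())}\n{comment or 'chromdpd frame'}\n")
    tags = np.where(np.asarray(species) == 0, "P", "S")
    for tag, (x, y, z) in zip(tags[keep], np.asarray(positions)[keep]):
        fh.write(f"{tag} {x:.6f} {y:.6f} {z:.6f}\n")


def read_pairs(path: str | Path) -> pd.DataFrame:
    """Read 4+-column TSV contact records (chrom1, pos1, chrom2, pos2).

    Lines starting with '#' are comments; malformed lines are skipped and
    counted in the log. Returns a DataFrame with the four canonical
    columns; positions are integers.
    """
    records = []
    bad = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                bad += 1
                continue
            try:
                records.append(
                    (parts[0], int(parts[1]), parts[2], int(parts[3]))
                )
            except ValueError:
                bad += 1
    if bad:
        logger.warning("read_pairs(%s): skipped %d malformed lines", path, bad)
    df = pd.DataFrame(records, columns=["chrom1", "pos1", "chrom2", "pos2"])
    df.attrs["n_malformed"] = bad
    return df


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """UCSC chrom.sizes: 2-column TSV of chromosome name and length."""
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            name, size = line.split()[:2]
            sizes[name] = int(size)
    return sizes


def write_structure(
    conf: Conformation,
    path: str | Path,
    format: Optional[str] = None,
    comment: str = "",
) -> None:
    """Write a conformation as XYZ or pseudo-atom PDB.

    XYZ: bead count, comment, then one ``P x y z`` line per bead (element
    P for polymer; chain index appended as a trailing column when there
    are several chains). PDB: one CA pseudo-atom per bead, one chain ID
    per polymer chain, coordinates multiplied by ``PDB_SCALE`` for viewer
    friendliness (stated in a REMARK).
    """
    path = Path(path)
    if format is None:
        format = "pdb" if path.suffix.lower() == ".pdb" else "xyz"
    if format == "xyz":
        lines = [str(conf.n_beads), comment or "chromdpd conformation"]
        multi = len(conf.chains) > 1
        for ci, (a, b) in enumerate(conf.chains):
            for i in range(a, b):
                x, y, z = conf.coords[i]
                row = f"P {x:.6f} {y:.6f} {z:.6f}"
                if multi:
                    row += f" {ci}"
                lines.append(row)
        path.write_text("\n".join(lines) + "\n")
        return
    if format == "pdb":
        if len(conf.chains) > len(_CHAIN_IDS):
            raise ValueError(
                f"more than {len(_CHAIN_IDS)} chains cannot be encoded as "
                "PDB chain IDs; use XYZ output"
            )
        lines = [
            f"REMARK   chromdpd model; coordinates are DPD lengths x {PDB_SCALE:g}"
        ]
        serial = 1
        for ci, (a, b) in enumerate(conf.chains):
            cid = _CHAIN_IDS[ci]
            for res, i in enumerate(range(a, b), start=1):
                x, y, z = conf.coords[i] * PDB_SCALE
                lines.append(
                    f"ATOM  {serial:5d}  CA  GLY {cid}{res % 10000:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
                )
                serial += 1
            lines.append(f"TER   {serial:5d}      GLY {cid}")
        lines.append("END")
        path.write_text("\n".join(lines) + "\n")
        return
    raise ValueError("format must be 'xyz' or 'pdb'")


def read_xyz(path: str | Path) -> Conformation:
    """Read an XYZ file written by :func:`write_structure`."""
    lines = Path(path).read_text().splitlines()
    n = int(lines[0].strip())
    coords = np.empty((n, 3))
    chain_col = []
    for k in range(n):
        parts = lines[2 + k].split()
        coords[k] = [float(v) for v in parts[1:4]]
        chain_col.append(int(parts[4]) if len(parts) > 4 else 0)
    chains = []
    start = 0
    for k in range(1, n + 1):
        if k == n or chain_col[k] != chain_col[k - 1]:
            chains.append((start, k))
            start = k
    return Conformation(coords, chains)


def write_contact_map(cmap: ContactMap, path: str | Path) -> None:
    """2-column TSV of bead-index pairs with an ``# n_beads = N`` header;
    a third multiplicity column when present."""
    lines = [f"# n_beads = {cmap.n_beads}"]
    mult = cmap.multiplicity
    for k, (i, j) in enumerate(cmap.pairs):
        if mult is not None:
            lines.append(f"{i}\t{j}\t{mult[k]}")
        else:
            lines.append(f"{i}\t{j}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_contact_map(path: str | Path) -> ContactMap:
    n_beads = None
    pairs = []
    mult = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "n_beads" in line:
                    n_beads = int(line.split("=")[1])
                continue
            parts = line.split("\t")
            pairs.append((int(parts[0]), int(parts[1])))
            if len(parts) > 2:
                mult.append(int(parts[2]))
    if n_beads is None:
        raise ValueError(f"{path}: missing '# n_beads = N' header")
    return ContactMap(
        n_beads,
        np.array(pairs, dtype=np.int64).reshape(-1, 2),
        multiplicity=np.array(mult, dtype=np.int64) if mult else None,
    )


def write_distance_map(values: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, values, fmt="%.6g")


def read_distance_map(path: str | Path) -> np.ndarray:
    return np.loadtxt(path)


# ---------------------------------------------------------------------------
# synthetic fixtures


def _powerlaw_separations(
    n_beads: int, n_contacts: int, decay: float, rng: np.random.Generator
) -> np.ndarray:
    """Genomic separations s in [2, n_beads-1] with P(s) ~ s**decay."""
    s = np.arange(2, n_beads)
    w = s.astype(float) ** decay
    w /= w.sum()
    return rng.choice(s, size=n_contacts, p=w)


def make_fixture(
    kind: str,
    path: str | Path,
    n_beads: int = 1000,
    contacts_per_bead: float = 0.5,
    decay: float = -1.0,
    resolution: int = 200_000,
    chrom: str = "chr1",
    missing_fraction: float = 0.0,
    seed: int = 0,
) -> Path:
    """Write a synthetic single-cell-like input file.

    ``kind``:
      - ``scHiC_pairs``: TSV contact records on one synthetic chromosome,
        with power-law contact-probability decay ``P(s) ~ s**decay`` in
        genomic separation and a total of
        ``round(contacts_per_bead * n_beads)`` unique binned contacts;
      - ``contact_map``: the same statistics as a binned bead-pair map;
      - ``distance_map``: a dense distance matrix of a random-walk
        conformation with a fraction of rows/columns missing (NaN), as an
        imaging-style measurement.

    Deterministic per seed; raises when the target density exceeds the
    number of admissible pairs.
    """
    path = Path(path)
    rng = np.random.default_rng(seed)
    n_target = int(np.floor(contacts_per_bead * n_beads + 0.5))
    max_pairs = (n_beads - 1) * (n_beads - 2) // 2  # |i-j| >= 2
    if kind in ("scHiC_pairs", "contact_map") and n_target > max_pairs:
        raise ValueError(
            f"cannot place {n_target} contacts among {max_pairs} pairs"
        )
    if kind in ("scHiC_pairs", "contact_map"):
        chosen: set[tuple[int, int]] = set()
        while len(chosen) < n_target:
            need = n_target - len(chosen)
            seps = _powerlaw_separations(n_beads, max(need * 2, 16), decay, rng)
            for s in seps:
                i = int(rng.integers(0, n_beads - s))
                chosen.add((i, i + int(s)))
                if len(chosen) == n_target:
                    break
        pairs = np.array(sorted(chosen), dtype=np.int64).reshape(-1, 2)
        if kind == "contact_map":
            write_contact_map(ContactMap(n_beads, pairs), path)
            return path
        lines = ["# synthetic single-cell contact records"]
        for i, j in pairs:
            pos1 = int(i) * resolution + int(rng.integers(0, resolution))
            pos2 = int(j) * resolution + int(rng.integers(0, resolution))
            lines.append(f"{chrom}\t{pos1}\t{chrom}\t{pos2}")
        path.write_text("\n".join(lines) + "\n")
        return path
    if kind == "distance_map":
        steps = rng.normal(size=(n_beads - 1, 3))
        steps /= np.linalg.norm(steps, axis=1, keepdims=True)
        coords = np.vstack([[0.0, 0.0, 0.0], np.cumsum(steps, axis=0)])
        d = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
        n_miss = int(round(missing_fraction * n_beads))
        miss = rng.choice(n_beads, size=n_miss, replace=False)
        d[miss, :] = np.nan
        d[:, miss] = np.nan
        write_distance_map(d, path)
        return path
    raise ValueError(
        "kind must be 'scHiC_pairs', 'contact_map' or 'distance_map'"
    )
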