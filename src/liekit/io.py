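"""Readers and writers for every file the pipeline touches.

Tabular formats are header-first TSV/CSV with ``#`` comment lines and dot
decimals; energies are kcal/mol throughout (no unit autodetection).  Parse
errors always carry the file path and 1-based line number.  Writers are
deterministic: identical inputs produce byte-identical files.

Coordinates are read from standard PDB files (single- or multi-MODEL) via
Biopython; only the first alternate location of a disordered atom is kept,
with a logged warning.

The packaged reference tables for the kojic-acid analog / tyrosinase set
(docking scores + IC50 for 16 analogs; four ensemble averages + reported
free-energy columns for 13 analogs) load through :func:`load_docking_table`,
:func:`load_lie_reference` and :func:`load_reference_dataset`.
"""

from __future__ import annotations

import csv
import logging
import re
from collections.abc import Iterable, Mapping, Sequence
from importlib.resources import files
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import LIEDataset, LigandEntry
from .energies import EnergySeries
from .exceptions import ParseError, ValidationError
from .geometry import AtomTable, CoordinateSet, Trajectory
from .residues import PerResidueSeries

logger = logging.getLogger(__name__)

__all__ = [
    "read_energy_table",
    "write_energy_table",
    "read_ligand_table",
    "write_ligand_table",
    "read_residue_table",
    "write_residue_table",
    "read_dataset_table",
    "write_dataset_table",
    "read_pdb_coords",
    "write_pdb_coords",
    "write_results",
    "load_docking_table",
    "load_lie_reference",
    "load_reference_dataset",
]

_FLOAT_FMT = "%.17g"  # lossless binary round-trip for doubles


def _read_rows(path, required: Sequence[str], delimiter: str | None = None):
    """Parse a commented, headered table; yield (header, [(lineno, cells)])."""
    path = Path(path)
    header: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    with open(path, newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if delimiter is None:  # sniff once, on the header line
                delimiter = "\t" if "\t" in line else ","
            cells = next(csv.reader([line], delimiter=delimiter))
            cells = [c.strip() for c in cells]
            if header is None:
                header = cells
                missing = [c for c in required if c not in header]
                if missing:
                    raise ParseError(
                        f"missing required column(s): {', '.join(missing)}",
                        str(path),
                        lineno,
                    )
                continue
            if len(cells) != len(header):
                raise ParseError(
                    f"expected {len(header)} fields, got {len(cells)}", str(path), lineno
                )
            rows.append((lineno, cells))
    if header is None:
        raise ParseError("no header row found", str(path))
    return header, rows


def _to_float(value: str, path: str, lineno: int, column: str) -> float:
    try:
        out = float(value)
    except ValueError:
        raise ParseError(f"non-numeric value {value!r} in column {column!r}", path, lineno)
    return out


def _to_int(value: str, path: str, lineno: int, column: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise ParseError(f"non-integer value {value!r} in column {column!r}", path, lineno)


# ---------------------------------------------------------------------------
# per-frame energy tables


def read_energy_table(path) -> list[EnergySeries]:
    """Read per-frame interaction energies into grouped :class:`EnergySeries`.

    Expected TSV columns: ``ligand_id state replica frame u_vdw u_ele``.
    Frames are sorted within each replica; a duplicated
    (ligand, state, replica, frame) key is an error.
    """
    required = ("ligand_id", "state", "replica", "frame", "u_vdw", "u_ele")
    header, rows = _read_rows(path, required, delimiter="\t")
    col = {name: header.index(name) for name in required}
    spath = str(path)
    seen: dict[tuple, int] = {}
    grouped: dict[tuple[str, str], dict[int, list[tuple[int, float, float]]]] = {}
    for lineno, cells in rows:
        ligand = cells[col["ligand_id"]]
        state = cells[col["state"]]
        if state not in ("bound", "free"):
            raise ParseError(f"state must be 'bound' or 'free', got {state!r}", spath, lineno)
        replica = _to_int(cells[col["replica"]], spath, lineno, "replica")
        frame = _to_int(cells[col["frame"]], spath, lineno, "frame")
        key = (ligand, state, replica, frame)
        if key in seen:
            raise ParseError(
                f"duplicate frame {key} (first seen at line {seen[key]})", spath, lineno
            )
        seen[key] = lineno
        u_vdw = _to_float(cells[col["u_vdw"]], spath, lineno, "u_vdw")
        u_ele = _to_float(cells[col["u_ele"]], spath, lineno, "u_ele")
        grouped.setdefault((ligand, state), {}).setdefault(replica, []).append(
            (frame, u_vdw, u_ele)
        )
    series = []
    for (ligand, state), replicas in sorted(grouped.items()):
        arrays = []
        for rep_id in sorted(replicas):
            samples = sorted(replicas[rep_id])
            arrays.append(np.array([[v, e] for _, v, e in samples]))
        series.append(EnergySeries(ligand_id=ligand, state=state, replicas=tuple(arrays)))
    return series


def write_energy_table(series: Iterable[EnergySeries], path) -> None:
    """Inverse of :func:`read_energy_table`; full-precision, deterministic."""
    with open(path, "w", newline="") as fh:
        fh.write("ligand_id\tstate\treplica\tframe\tu_vdw\tu_ele\n")
        for s in sorted(series, key=lambda s: (s.ligand_id, s.state)):
            for rep_id, rep in enumerate(s.replicas):
                for frame, (v, e) in enumerate(rep):
                    fh.write(
                        f"{s.ligand_id}\t{s.state}\t{rep_id}\t{frame}\t"
                        f"{_FLOAT_FMT % v}\t{_FLOAT_FMT % e}\n"
                    )


# ---------------------------------------------------------------------------
# ligand tables


_LIGAND_OPTIONAL = ("ic50_um", "hydroxyl_count", "net_charge", "docking_score")


def read_ligand_table(path) -> list[LigandEntry]:
    """Read a ligand table (CSV or TSV, sniffed from the header).

    ``ligand_id`` is required; ``ic50_um``, ``hydroxyl_count``,
    ``net_charge`` and ``docking_score`` are optional columns, and empty
    cells mean absent.
    """
    header, rows = _read_rows(path, ("ligand_id",))
    col = {name: header.index(name) for name in header}
    spath = str(path)
    entries: list[LigandEntry] = []
    seen: dict[str, int] = {}
    for lineno, cells in rows:
        ligand_id = cells[col["ligand_id"]]
        if ligand_id in seen:
            raise ParseError(
                f"duplicate ligand id {ligand_id!r} (first at line {seen[ligand_id]})",
                spath,
                lineno,
            )
        seen[ligand_id] = lineno
        kwargs: dict[str, object] = {"ligand_id": ligand_id}
        for name in _LIGAND_OPTIONAL:
            if name in col and cells[col[name]] != "":
                conv = _to_int if name in ("hydroxyl_count", "net_charge") else _to_float
                kwargs[name] = conv(cells[col[name]], spath, lineno, name)
        try:
            entries.append(LigandEntry(**kwargs))
        except ValidationError as exc:
            raise ParseError(str(exc), spath, lineno) from exc
    return entries


def write_ligand_table(entries: Iterable[LigandEntry], path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("ligand_id\tic50_um\thydroxyl_count\tnet_charge\tdocking_score\n")
        for e in sorted(entries, key=lambda e: e.ligand_id):
            cells = [e.ligand_id]
            for value, fmt in (
                (e.ic50_um, _FLOAT_FMT),
                (e.hydroxyl_count, "%d"),
                (e.net_charge, "%d"),
                (e.docking_score, _FLOAT_FMT),
            ):
                cells.append("" if value is None else fmt % value)
            fh.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# per-residue tables


def read_residue_table(path) -> list[PerResidueSeries]:
    """Read per-frame, per-residue energies.

    Expected TSV columns: ``ligand_id replica frame residue_id u_vdw
    u_ele``.  Residue order per ligand is first-appearance order; every
    frame must list every residue exactly once.
    """
    required = ("ligand_id", "replica", "frame", "residue_id", "u_vdw", "u_ele")
    header, rows = _read_rows(path, required, delimiter="\t")
    col = {name: header.index(name) for name in required}
    spath = str(path)
    order: dict[str, list[str]] = {}
    data: dict[str, dict[int, dict[int, dict[str, tuple[float, float]]]]] = {}
    for lineno, cells in rows:
        ligand = cells[col["ligand_id"]]
        replica = _to_int(cells[col["replica"]], spath, lineno, "replica")
        frame = _to_int(cells[col["frame"]], spath, lineno, "frame")
        residue = cells[col["residue_id"]]
        v = _to_float(cells[col["u_vdw"]], spath, lineno, "u_vdw")
        e = _to_float(cells[col["u_ele"]], spath, lineno, "u_ele")
        res_order = order.setdefault(ligand, [])
        if residue not in res_order:
            res_order.append(residue)
        frame_map = data.setdefault(ligand, {}).setdefault(replica, {}).setdefault(frame, {})
        if residue in frame_map:
            raise ParseError(
                f"duplicate residue {residue!r} in frame {frame} of replica {replica}",
                spath,
                lineno,
            )
        frame_map[residue] = (v, e)
    series = []
    for ligand in sorted(data):
        residues = order[ligand]
        replicas = []
        for rep_id in sorted(data[ligand]):
            frames = data[ligand][rep_id]
            arr = np.empty((len(frames), len(residues), 2))
            for i, frame in enumerate(sorted(frames)):
                missing = [r for r in residues if r not in frames[frame]]
                if missing:
                    raise ParseError(
                        f"ligand {ligand!r} replica {rep_id} frame {frame}: "
                        f"missing residues {missing}",
                        spath,
                    )
                for j, residue in enumerate(residues):
                    arr[i, j] = frames[frame][residue]
            replicas.append(arr)
        series.append(
            PerResidueSeries(
                ligand_id=ligand, residue_ids=tuple(residues), replicas=tuple(replicas)
            )
        )
    return series


def write_residue_table(series: Iterable[PerResidueSeries], path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("ligand_id\treplica\tframe\tresidue_id\tu_vdw\tu_ele\n")
        for s in sorted(series, key=lambda s: s.ligand_id):
            for rep_id, rep in enumerate(s.replicas):
                for frame in range(rep.shape[0]):
                    for j, residue in enumerate(s.residue_ids):
                        v, e = rep[frame, j]
                        fh.write(
                            f"{s.ligand_id}\t{rep_id}\t{frame}\t{residue}\t"
                            f"{_FLOAT_FMT % v}\t{_FLOAT_FMT % e}\n"
                        )


# ---------------------------------------------------------------------------
# per-ligand dataset tables


def read_dataset_table(path) -> LIEDataset:
    """Read a per-ligand averages table into an :class:`LIEDataset`.

    Required columns: ``ligand_id free_vdw free_ele bound_vdw bound_ele``;
    optional: per-average ``*_sem`` and the ligand-record columns.
    """
    required = ("ligand_id", "free_vdw", "free_ele", "bound_vdw", "bound_ele")
    header, rows = _read_rows(path, required)
    spath = str(path)
    records = []
    for lineno, cells in rows:
        rec = {}
        for name, value in zip(header, cells):
            if name == "ligand_id":
                rec[name] = value
            elif value == "":
                rec[name] = np.nan
            else:
                rec[name] = _to_float(value, spath, lineno, name)
        records.append(rec)
    if not records:
        return LIEDataset(())
    try:
        return LIEDataset.from_dataframe(pd.DataFrame(records))
    except ValidationError as exc:
        raise ParseError(str(exc), spath) from exc


def write_dataset_table(dataset: LIEDataset, path) -> None:
    df = dataset.to_dataframe()
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(df.columns) + "\n")
        for _, row in df.iterrows():
            cells = []
            for name in df.columns:
                value = row[name]
                if name == "ligand_id":
                    cells.append(str(value))
                elif pd.isna(value):
                    cells.append("")
                elif name in ("hydroxyl_count", "net_charge"):
                    cells.append("%d" % value)
                else:
                    cells.append(_FLOAT_FMT % value)
            fh.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# PDB coordinates


def read_pdb_coords(path, ligand_resnames: Sequence[str] = ("LIG",)) -> Trajectory:
    """Read a PDB file into a :class:`Trajectory` (one frame per MODEL).

    Group tags: HETATM copper atoms -> ``metal``; HETATM residues named in
    ``ligand_resnames`` -> ``ligand``; everything else -> ``protein``.
    Elements come from the element column, falling back to the atom name.
    Only the first alternate location of a disordered atom is kept.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("traj", str(path))
    except Exception as exc:  # Biopython raises bare Exceptions on bad coords
        raise ParseError(f"unparseable PDB file: {exc}", str(path)) from exc
    ligand_resnames = {name.upper() for name in ligand_resnames}

    frames = []
    atom_rows = None
    for model in structure:
        rows = []
        coords = []
        for chain in model:
            for residue in chain:
                hetfield, resseq, _ = residue.id
                is_het = hetfield.strip() != ""
                resname = residue.get_resname().strip()
                for atom in residue:
                    if atom.is_disordered():
                        altloc_ids = sorted(atom.disordered_get_id_list())
                        if len(altloc_ids) > 1:
                            logger.warning(
                                "%s: atom %s %s%s has altlocs %s; keeping %r",
                                path, atom.get_id(), resname, resseq,
                                altloc_ids, altloc_ids[0],
                            )
                        atom = atom.disordered_get(altloc_ids[0])
                    element = (atom.element or "").strip().upper()
                    if not element:
                        element = re.sub(r"[^A-Za-z]", "", atom.get_name())[:1].upper()
                    if is_het and element == "CU":
                        group = "metal"
                    elif is_het and resname.upper() in ligand_resnames:
                        group = "ligand"
                    else:
                        group = "protein"
                    rows.append(
                        (atom.serial_number, atom.get_name(), f"{resname}{resseq}", element, group)
                    )
                    coords.append(atom.coord)
        if atom_rows is None:
            atom_rows = rows
        elif len(rows) != len(atom_rows):
            raise ParseError(
                f"inconsistent atom counts across models: {len(atom_rows)} vs {len(rows)}",
                str(path),
            )
        frames.append(np.array(coords, dtype=float))
    if atom_rows is None or not frames:
        raise ParseError("no atoms found", str(path))
    ids, names, residues, elements, groups = (np.array(c) for c in zip(*atom_rows))
    atoms = AtomTable(
        ids=ids.astype(int),
        names=names,
        residue_ids=residues,
        elements=elements,
        groups=groups,
    )
    return Trajectory(atoms=atoms, coords=np.stack(frames))


_RES_LABEL = re.compile(r"^(?P<name>.*?)(?P<seq>\d+)?$")


def write_pdb_coords(traj: Trajectory, path) -> None:
    """Write a trajectory as a (multi-MODEL) PDB file with 8.3 coordinates."""
    multi = traj.n_frames > 1
    with open(path, "w") as fh:
        for i in range(traj.n_frames):
            if multi:
                fh.write(f"MODEL     {i + 1:4d}\n")
            for j in range(traj.n_atoms):
                a = traj.atoms
                record = "ATOM  " if a.groups[j] == "protein" else "HETATM"
                m = _RES_LABEL.match(str(a.residue_ids[j]))
                resname = (m.group("name") or "UNK")[:3].upper()
                resseq = int(m.group("seq") or 1)
                name = str(a.names[j])
                name_field = name.ljust(4) if len(name) >= 4 else f" {name:<3}"
                x, y, z = traj.coords[i, j]
                fh.write(
                    f"{record}{int(a.ids[j]):5d} {name_field} {resname:>3} A{resseq:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {str(a.elements[j]):>2}\n"
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# rendered result tables


def write_results(tables: Mapping[str, pd.DataFrame], prefix) -> list[Path]:
    """Write report tables as deterministic 2-decimal TSV files.

    Each table goes to ``<prefix>_<name>.tsv`` with the given column order,
    rows sorted by ``ligand_id`` when present, floats rendered with two
    decimals, and byte-identical output for identical inputs.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in sorted(tables.items()):
        out = prefix.parent / f"{prefix.name}_{name}.tsv"
        df = df.copy()
        if "ligand_id" in df.columns:
            df = df.sort_values("ligand_id", kind="stable")
        with open(out, "w", newline="") as fh:
            fh.write("\t".join(str(c) for c in df.columns) + "\n")
            for _, row in df.iterrows():
                cells = []
                for value in row:
                    if isinstance(value, (float, np.floating)):
                        cells.append("" if pd.isna(value) else f"{value:.2f}")
                    else:
                        cells.append(str(value))
                fh.write("\t".join(cells) + "\n")
        paths.append(out)
    return paths


# ---------------------------------------------------------------------------
# packaged reference tables


def _data_path(name: str):
    return files("liekit") / "data" / name


def load_docking_table() -> list[LigandEntry]:
    """Docking scores and IC50 values for the 16 kojic-acid analogs."""
    return read_ligand_table(_data_path("ka_docking_ic50.tsv"))


def load_lie_reference() -> pd.DataFrame:
    """The 13-analog reference table: four ensemble averages with replica
    standard errors plus the reported LIE and experimental free-energy
    columns (``dg_lie_ref``, ``dg_lie_sem_ref``, ``dg_exp_ref``)."""
    header, rows = _read_rows(_data_path("ka_lie_averages.tsv"), ("ligand_id",))
    records = []
    for _, cells in rows:
        rec = dict(zip(header, cells))
        records.append(
            {k: (v if k == "ligand_id" else float(v)) for k, v in rec.items()}
        )
    return pd.DataFrame(records)


def load_reference_dataset() -> LIEDataset:
    """The 13-analog averages joined with their IC50 and docking records."""
    averages = load_lie_reference()
    ligands = {e.ligand_id: e for e in load_docking_table()}
    df = averages.drop(columns=["dg_lie_ref", "dg_lie_sem_ref", "dg_exp_ref"])
    df["ic50_um"] = [ligands[i].ic50_um for i in df["ligand_id"]]
    df["docking_score"] = [ligands[i].docking_score for i in df["ligand_id"]]
    return LIEDataset.from_dataframe(df)
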