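"""Text-format readers and writers.

Formats:

* system schema -- a sectioned key/value + table format with
  ``[meta]``, ``[atom_types]``, ``[atoms]``, ``[bonds]``, ``[angles]``
  sections (atom ids are 1-based in files, 0-based in memory; floats are
  written with ``repr`` so read(write(x)) round-trips exactly);
* multi-frame XYZ for coordinates (the comment line carries step and
  replica index);
* work-sample CSV (columns direction, delta_u, bias; ``# key=value``
  header comments carry beta and soft-core provenance);
* energy/dU log CSV (frame, step, level_A, level_B, U_A, U_B, delta_U plus
  one column per energy-breakdown component);
* replica-exchange log CSV;
* free-energy results as JSON with full provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .energy import EnergyBreakdown
from .estimators import FreeEnergyResult, WorkSampleSet
from .sampling import ReplicaLog
from .systems import (
    AngleParam,
    Atom,
    AtomType,
    BondParam,
    Frame,
    ParameterSet,
    SystemModel,
    Topology,
    ValidationError,
)

__all__ = [
    "write_system",
    "read_system",
    "write_xyz",
    "read_xyz",
    "write_work_samples",
    "read_work_samples",
    "write_energy_log",
    "read_energy_log",
    "write_replica_log",
    "write_result_json",
    "read_result_json",
]

_MINUS = "−"  # normalized to ASCII minus on read


def _f(x: float) -> str:
    return repr(float(x))


def write_system(model: SystemModel, path) -> None:
    """Write a model in the system schema (full float precision)."""
    lines = ["# bookend system schema v1", "", "[meta]", f"level = {model.level}"]
    if model.box_edge is not None:
        lines.append(f"box_edge = {_f(model.box_edge)}")
    for key, value in sorted(model.metadata.items()):
        lines.append(f"meta.{key} = {value}")
    lines += ["", "[atom_types]",
              "# name mass charge lj_epsilon lj_rmin_half polarizability drude_spring"]
    for name in sorted(model.parameters.atom_types):
        t = model.parameters.atom_types[name]
        lines.append(
            f"{t.name} {_f(t.mass)} {_f(t.charge)} {_f(t.lj_epsilon)} "
            f"{_f(t.lj_rmin_half)} {_f(t.polarizability)} {_f(t.drude_spring)}"
        )
    lines += ["", "[atoms]", "# id type group"]
    for a in model.topology.atoms:
        lines.append(f"{a.index + 1} {a.type_name} {a.group}")
    lines += ["", "[bonds]", "# i j k_b b0 [morse_depth]"]
    for i, j in model.topology.bonds:
        p = model.parameters.bond_param(
            model.topology.atoms[i].type_name, model.topology.atoms[j].type_name
        )
        extra = f" {_f(p.morse_depth)}" if p.morse_depth is not None else ""
        lines.append(f"{i + 1} {j + 1} {_f(p.k_b)} {_f(p.b0)}{extra}")
    lines += ["", "[angles]", "# i j k k_theta theta0"]
    for i, j, k in model.topology.angles:
        p = model.parameters.angle_param(
            model.topology.atoms[i].type_name,
            model.topology.atoms[j].type_name,
            model.topology.atoms[k].type_name,
        )
        lines.append(f"{i + 1} {j + 1} {k + 1} {_f(p.k_theta)} {_f(p.theta0)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_system(path) -> SystemModel:
    """Read a model from the system schema."""
    section = None
    level = "MM"
    box_edge = None
    metadata: dict = {}
    types: dict[str, AtomType] = {}
    atoms: list[Atom] = []
    bond_rows: list[tuple[int, int, BondParam]] = []
    angle_rows: list[tuple[int, int, int, AngleParam]] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.replace(_MINUS, "-").strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1]
            continue
        if section == "meta":
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key == "level":
                level = value
            elif key == "box_edge":
                box_edge = float(value)
            elif key.startswith("meta."):
                metadata[key[5:]] = value
            continue
        parts = line.split()
        if section == "atom_types":
            name = parts[0]
            vals = [float(v) for v in parts[1:]]
            types[name] = AtomType(name, *vals)
        elif section == "atoms":
            atoms.append(Atom(int(parts[0]) - 1, parts[1], parts[2]))
        elif section == "bonds":
            i, j = int(parts[0]) - 1, int(parts[1]) - 1
            morse = float(parts[4]) if len(parts) > 4 else None
            bond_rows.append((i, j, BondParam(float(parts[2]), float(parts[3]), morse)))
        elif section == "angles":
            i, j, k = (int(p) - 1 for p in parts[:3])
            angle_rows.append((i, j, k, AngleParam(float(parts[3]), float(parts[4]))))
        else:
            raise ValidationError(f"line outside a known section: {raw!r}")
    tname = {a.index: a.type_name for a in sorted(atoms, key=lambda a: a.index)}
    bond_params: dict[tuple[str, str], BondParam] = {}
    bonds = []
    for i, j, p in bond_rows:
        key = (tname[i], tname[j])
        if bond_params.setdefault(key, p) != p and bond_params.get((tname[j], tname[i])) != p:
            raise ValidationError(f"conflicting bond parameters for type pair {key}")
        bonds.append((i, j))
    angle_params: dict[tuple[str, str, str], AngleParam] = {}
    angles = []
    for i, j, k, p in angle_rows:
        key = (tname[i], tname[j], tname[k])
        if angle_params.setdefault(key, p) != p:
            raise ValidationError(f"conflicting angle parameters for type triple {key}")
        angles.append((i, j, k))
    topo = Topology(
        sorted(atoms, key=lambda a: a.index),
        bonds,
        angles,
        Topology.auto_exclusions(bonds, angles),
    )
    model = SystemModel(
        topo, ParameterSet(types, bond_params, angle_params), level=level, box_edge=box_edge
    )
    model.metadata = metadata
    return model


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------


def write_xyz(frames, labels, path) -> None:
    """Write frames as multi-frame XYZ; the comment line carries
    ``step=<n> replica=<r>``.  ``labels`` are per-atom element-like names."""
    out = []
    for frame in frames:
        x = frame.coordinates
        out.append(str(len(labels)))
        out.append(f"step={frame.step} replica={frame.replica_index}")
        for lbl, row in zip(labels, x):
            out.append(f"{lbl} {_f(row[0])} {_f(row[1])} {_f(row[2])}")
    Path(path).write_text("\n".join(out) + "\n")


def read_xyz(path) -> list[Frame]:
    lines = Path(path).read_text().splitlines()
    frames = []
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        n = int(lines[pos].strip())
        comment = lines[pos + 1]
        fields = dict(
            kv.split("=") for kv in comment.split() if "=" in kv
        )
        coords = np.array(
            [[float(v) for v in lines[pos + 2 + i].split()[1:4]] for i in range(n)]
        )
        frames.append(
            Frame(coords, step=int(fields.get("step", 0)),
                  replica_index=int(fields.get("replica", 0)))
        )
        pos += 2 + n
    return frames


# ---------------------------------------------------------------------------
# CSV logs
# ---------------------------------------------------------------------------


def write_work_samples(samples: WorkSampleSet, path, provenance: dict | None = None) -> None:
    rows = []
    for i, du in enumerate(samples.forward):
        b = 0.0 if samples.bias_forward is None else samples.bias_forward[i]
        rows.append(("forward", du, b))
    if samples.reverse is not None:
        for i, du in enumerate(samples.reverse):
            b = 0.0 if samples.bias_reverse is None else samples.bias_reverse[i]
            rows.append(("reverse", du, b))
    header = [f"# beta={_f(samples.beta)}"]
    for key, value in (provenance or {}).items():
        header.append(f"# {key}={value}")
    df = pd.DataFrame(rows, columns=["direction", "delta_u", "bias"])
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, index=False)


def read_work_samples(path) -> WorkSampleSet:
    beta = 1.0
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for line in lines:
        if line.startswith("#"):
            body_start += 1
            if "beta=" in line:
                beta = float(line.split("beta=")[1].split()[0])
        else:
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])))
    fwd = df[df.direction == "forward"]
    rev = df[df.direction == "reverse"]
    has_bias = bool(np.any(df.bias != 0.0))
    return WorkSampleSet(
        fwd.delta_u.to_numpy(),
        rev.delta_u.to_numpy() if len(rev) else None,
        fwd.bias.to_numpy() if has_bias else None,
        (rev.bias.to_numpy() if len(rev) else None) if has_bias else None,
        beta=beta,
    )


_BREAKDOWN_COLS = [
    "solute_solute",
    "solute_solvent_elec",
    "solute_solvent_vdw",
    "solvent_solvent",
    "bonded_solute",
    "drude_spring",
]


def write_energy_log(rows: list[dict], path) -> None:
    """Write a per-frame dU log.  Each row needs frame, step, level_A,
    level_B, U_A, U_B, delta_U and a 'breakdown' EnergyBreakdown (of the
    B-level evaluation)."""
    records = []
    for row in rows:
        rec = {k: row[k] for k in ("frame", "step", "level_A", "level_B", "U_A", "U_B", "delta_U")}
        bd: EnergyBreakdown = row["breakdown"]
        for col in _BREAKDOWN_COLS:
            rec[col] = getattr(bd, col)
        records.append(rec)
    pd.DataFrame(records).to_csv(path, index=False)


def read_energy_log(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_replica_log(log: ReplicaLog, path) -> None:
    rows = []
    for record in log.records:
        for att in record["attempts"]:
            rows.append(
                {
                    "sweep": record["sweep"],
                    "permutation": "-".join(str(p) for p in record["permutation"]),
                    **att,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_result_json(result: FreeEnergyResult, path) -> None:
    Path(path).write_text(json.dumps(result.to_dict(), indent=2) + "\n")


def read_result_json(path) -> dict:
    return json.loads(Path(path).read_text())
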