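"""Persistence: truth-table sets, neuron witnesses, capacity results, fixtures.

Formats are text-first: truth tables as JSON-lines records
``{"n": int, "table_hex": str}`` (hex of the packed table, bit k = f(k)),
neurons as JSON, capacity witnesses as CSV.  HDF5 export of capacity
results is available when h5py is installed.
"""

from __future__ import annotations

import csv
import hashlib
import json
import os
from typing import List

from .booleans import BooleanFunction, and_function, fbp_family, nand2, xor2
from .capacity import CapacityResult, SearchSpace
from .neuron import Activation, Subunit, TwoStageNeuron, truth_table

__all__ = [
    "write_function_set",
    "read_function_set",
    "neuron_to_dict",
    "neuron_from_dict",
    "write_neuron",
    "read_neuron",
    "write_witness_csv",
    "read_witness_csv",
    "save_capacity_hdf5",
    "load_capacity_hdf5",
    "generate_fixtures",
    "EXAMPLE_WITNESSES",
]


# ---------------------------------------------------------------- functions

def write_function_set(path: str, funcs: List[BooleanFunction]) -> None:
    with open(path, "w") as fh:
        for f in funcs:
            fh.write(json.dumps({"n": f.n_vars, "table_hex": f.to_hex()}) + "\n")


def read_function_set(path: str) -> List[BooleanFunction]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                out.append(BooleanFunction.from_hex(rec["n"], rec["table_hex"]))
            except (json.JSONDecodeError, KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: bad function record: {exc}")
    return out


# ------------------------------------------------------------------ neurons

def neuron_to_dict(m: TwoStageNeuron) -> dict:
    return {
        "n": m.n_vars,
        "soma_threshold": m.soma_threshold,
        "subunits": [
            {
                "kind": su.activation.kind,
                "theta": su.activation.theta,
                "height": su.activation.height,
                "weights": list(su.weights),
            }
            for su in m.subunits
        ],
    }


def neuron_from_dict(d: dict) -> TwoStageNeuron:
    subunits = tuple(
        Subunit(
            tuple(su["weights"]),
            Activation(su["kind"], su.get("theta", 0), su.get("height", 0)),
        )
        for su in d["subunits"]
    )
    return TwoStageNeuron(d["n"], subunits, d["soma_threshold"])


def write_neuron(path: str, m: TwoStageNeuron) -> None:
    with open(path, "w") as fh:
        json.dump(neuron_to_dict(m), fh, indent=1)
        fh.write("\n")


def read_neuron(path: str) -> TwoStageNeuron:
    with open(path) as fh:
        try:
            return neuron_from_dict(json.load(fh))
        except (json.JSONDecodeError, KeyError, ValueError) as exc:
            raise ValueError(f"{path}: bad neuron record: {exc}")


# ---------------------------------------------------------- capacity results

_CSV_FIELDS = ["canonical_hex", "n", "soma_threshold", "subunits_json"]


def write_witness_csv(path: str, result: CapacityResult) -> None:
    """One row per representative class found, with its witness neuron."""
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=_CSV_FIELDS)
        w.writeheader()
        for t in result.found:
            m = result.witnesses[t]
            w.writerow({
                "canonical_hex": format(int(t), "x"),
                "n": m.n_vars,
                "soma_threshold": m.soma_threshold,
                "subunits_json": json.dumps(neuron_to_dict(m)["subunits"]),
            })


def read_witness_csv(path: str) -> dict:
    """Canonical table -> witness neuron, as written by write_witness_csv."""
    out = {}
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.DictReader(fh), 2):
            try:
                m = neuron_from_dict({
                    "n": int(row["n"]),
                    "soma_threshold": int(row["soma_threshold"]),
                    "subunits": json.loads(row["subunits_json"]),
                })
                out[int(row["canonical_hex"], 16)] = m
            except (KeyError, ValueError, json.JSONDecodeError) as exc:
                raise ValueError(f"{path}:{lineno}: bad witness row: {exc}")
    return out


_KIND_CODE = {"linear": 0, "spiking": 1, "saturating": 2}
_CODE_KIND = {v: k for k, v in _KIND_CODE.items()}


def save_capacity_hdf5(path: str, result: CapacityResult) -> None:
    """Archive a capacity result (tables + witness parameter matrix)."""
    import numpy as np

    try:
        import h5py
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "HDF5 export needs h5py; install dendricap[hdf5] or use CSV/JSONL"
        ) from exc
    n = result.space.n_vars
    rows = []
    for t in result.found:
        m = result.witnesses[t]
        wsoma = list(m.subunits[0].weights)
        if len(m.subunits) > 1:
            su = m.subunits[1]
            rows.append(
                [int(t)] + wsoma + list(su.weights)
                + [su.activation.theta, su.activation.height,
                   m.soma_threshold, _KIND_CODE[su.activation.kind]]
            )
        else:
            rows.append([int(t)] + wsoma + [0] * n + [0, 0, m.soma_threshold, 0])
    with h5py.File(path, "w") as h5:
        h5.create_dataset("tables", data=np.array(result.found, dtype=np.uint64))
        h5.create_dataset("witnesses", data=np.array(rows, dtype=np.int64))
        for k, v in vars(result.space).items():
            h5.attrs[k] = v


def load_capacity_hdf5(path: str) -> CapacityResult:
    try:
        import h5py
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading HDF5 results needs h5py") from exc
    with h5py.File(path, "r") as h5:
        attrs = dict(h5.attrs)
        space = SearchSpace(
            n_vars=int(attrs["n_vars"]),
            model_kind=str(attrs["model_kind"]),
            w_max_soma=int(attrs["w_max_soma"]),
            w_max_dend=int(attrs["w_max_dend"]),
            theta_max=int(attrs["theta_max"]),
            h_max=int(attrs["h_max"]),
            soma_threshold_max=int(attrs["soma_threshold_max"]),
            validate_activations=bool(attrs["validate_activations"]),
        )
        n = space.n_vars
        witnesses = {}
        for row in h5["witnesses"][...]:
            row = [int(v) for v in row]
            t = row[0]
            wsoma = tuple(row[1:1 + n])
            wd = tuple(row[1 + n:1 + 2 * n])
            theta, h, Theta, code = row[1 + 2 * n:]
            subunits = [Subunit(wsoma, Activation("linear"))]
            if code != 0:
                subunits.append(Subunit(wd, Activation(_CODE_KIND[code], theta, h)))
            witnesses[t] = TwoStageNeuron(n, tuple(subunits), Theta)
        found = tuple(int(v) for v in h5["tables"][...])
    return CapacityResult(space=space, found=found, witnesses=witnesses)


# ----------------------------------------------------------------- fixtures

def _eq1(wsoma, wdend, kind, theta, h, Theta) -> TwoStageNeuron:
    return TwoStageNeuron(
        4,
        (
            Subunit(wsoma, Activation("linear")),
            Subunit(wdend, Activation(kind, theta, h)),
        ),
        Theta,
    )


# Hand-checkable linear-plus-one-subunit witnesses for the three binding
# problems, one per dendritic family.  Each is verified against its table in
# the test suite and when fixtures are generated.
EXAMPLE_WITNESSES = {
    "fbp_spiking": _eq1((2, 2, 0, 0), (0, 0, 1, 1), "spiking", 2, 4, 4),
    "fbp_saturating": _eq1((0, 2, 1, 1), (4, 0, 2, 2), "saturating", 4, 4, 6),
    "dfbp_spiking": _eq1((2, 2, 1, 1), (0, 0, 1, 1), "spiking", 1, 2, 5),
    "dfbp_saturating": _eq1((0, 0, 1, 1), (3, 3, 1, 1), "saturating", 4, 4, 5),
    "pfbp_spiking": _eq1((0, 1, 2, 1), (1, 1, 0, 0), "spiking", 2, 3, 3),
    "pfbp_saturating": _eq1((1, 1, 2, 0), (0, 1, 0, 1), "saturating", 1, 2, 4),
}


def generate_fixtures(out_dir: str) -> dict:
    """Write the reference tables and witnesses; return the manifest.

    Deterministic: regenerating produces byte-identical files.  The
    manifest maps each file name to its sha256 checksum and is also written
    to ``manifest.json``.
    """
    os.makedirs(out_dir, exist_ok=True)
    fam = fbp_family()
    tables = {
        "and2": and_function(2),
        "nand2": nand2(),
        "xor2": xor2(),
        "fbp": fam["fbp"],
        "dfbp": fam["dfbp"],
        "pfbp": fam["pfbp"],
    }
    manifest = {}
    for name, f in tables.items():
        path = os.path.join(out_dir, f"{name}.jsonl")
        write_function_set(path, [f])
        manifest[f"{name}.jsonl"] = _sha256(path)
    for name, m in EXAMPLE_WITNESSES.items():
        target = fam[name.split("_")[0]]
        if truth_table(m).table != target.table:
            raise AssertionError(f"fixture witness {name} does not reproduce its table")
        path = os.path.join(out_dir, f"{name}.json")
        write_neuron(path, m)
        manifest[f"{name}.json"] = _sha256(path)
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()
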