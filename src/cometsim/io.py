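"""Config and tabular I/O: circuit YAML, dose-grid CSV, landscape export,
run manifests.

Circuit YAML schema::

    units:
      - {promoter: CMV, protein: VP64-ZF1, dose: 10, label: ZFa}   # dose in ng
    sensors:
      - {kind: intracellular-dimerizer, released_tf: VP64-ZF2,
         ligand: ABA, leak_fraction: 0.001}
    ligands: [rapamycin]
    reporter: mKate2            # or a list for MIMO
    dose_unit: ng               # ng | copies
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import replace
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .circuit import Circuit, SensorUnit, TranscriptionUnit
from .parts import parse_protein_name
from .simulate import DoseResponse, Landscape

__all__ = [
    "circuit_from_yaml",
    "circuit_to_yaml",
    "load_dose_grid",
    "landscape_to_csv",
    "dose_response_to_csv",
    "run_manifest",
]


def circuit_from_yaml(source) -> Circuit:
    """Load a circuit from a YAML file path, file object or string."""
    if hasattr(source, "read"):
        doc = yaml.safe_load(source)
    elif isinstance(source, str) and "\n" in source:
        doc = yaml.safe_load(source)
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    units = []
    for u in doc.get("units", []):
        prot = parse_protein_name(u["protein"])
        if "stability_multiplier" in u:
            prot = replace(prot, stability_multiplier=float(u["stability_multiplier"]))
        units.append(
            TranscriptionUnit(
                promoter=u["promoter"],
                protein=prot,
                dose=float(u.get("dose", 0.0)),
                label=u.get("label", ""),
            )
        )
    sensors = [
        SensorUnit(
            kind=s["kind"],
            released_tf=s["released_tf"],
            ligand=s["ligand"],
            leak_fraction=float(s.get("leak_fraction", 0.0)),
            release_rate=s.get("release_rate"),
            label=s.get("label", ""),
        )
        for s in doc.get("sensors", [])
    ]
    reporter = doc.get("reporter", [])
    reporters = (reporter,) if isinstance(reporter, str) else tuple(reporter)
    return Circuit(
        units=tuple(units),
        sensors=tuple(sensors),
        ligands_present=frozenset(doc.get("ligands", [])),
        reporters=reporters,
        dose_unit=doc.get("dose_unit", "ng"),
    )


def circuit_to_yaml(circuit: Circuit, path=None) -> str:
    doc = {
        "units": [
            {
                "promoter": u.promoter.name,
                "protein": u.protein.name,
                "dose": u.dose,
                "label": u.label,
                **(
                    {"stability_multiplier": u.protein.stability_multiplier}
                    if u.protein.stability_multiplier != 1.0
                    else {}
                ),
            }
            for u in circuit.units
        ],
        "sensors": [
            {
                "kind": s.kind,
                "released_tf": s.released_tf.name,
                "ligand": s.ligand,
                "leak_fraction": s.leak_fraction,
                **({"release_rate": s.release_rate} if s.release_rate else {}),
                "label": s.label,
            }
            for s in circuit.sensors
        ],
        "ligands": sorted(circuit.ligands_present),
        "reporter": list(circuit.reporters),
        "dose_unit": circuit.dose_unit,
    }
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def load_dose_grid(path) -> pd.DataFrame:
    """Long-format dose design CSV with columns ``unit, dose[, replicate]``."""
    df = pd.read_csv(path)
    missing = {"unit", "dose"} - set(df.columns)
    if missing:
        raise ValueError(f"dose grid is missing columns {sorted(missing)}")
    return df


def dose_response_to_csv(dr: DoseResponse, path) -> None:
    pd.DataFrame(
        {
            "unit": dr.input_unit,
            "dose": dr.doses,
            "output": dr.outputs,
            "readout": dr.readout,
            "dose_unit": dr.dose_unit,
        }
    ).to_csv(path, index=False)


def landscape_to_csv(ls: Landscape, path) -> None:
    """Matrix CSV: rows indexed by input-A dose, columns by input-B dose."""
    df = pd.DataFrame(ls.values, index=ls.grid_a, columns=ls.grid_b)
    df.index.name = f"{ls.input_units[0]} ({ls.dose_unit})"
    df.to_csv(path)


def run_manifest(seed: Optional[int] = None, **extra) -> dict:
    """Reproducibility manifest (parameter hash, seed, package version)."""
    from . import __version__
    from .registry import default_params

    params = default_params()
    digest = hashlib.sha256(
        json.dumps(params, sort_keys=True).encode()
    ).hexdigest()[:16]
    return {
        "cometsim_version": __version__,
        "parameter_hash": digest,
        "seed": seed,
        **extra,
    }
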