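"""File formats, run configuration and persistence.

Plain-text interchange only: PSMILES lists are one string per line with
``#`` comments; property tables are CSV with the schema
``psmiles_1, psmiles_2, c_1, c_2, property, value`` (blank second
comonomer for homopolymers); models live in directories of JSON + npz
(encoder) or joblib (predictors).  Every CLI run serializes its
resolved :class:`RunConfig` next to its outputs so results can be
reproduced from the seed.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
import os

import joblib

from .properties import PolymerRecord, REGISTRY, MetaLearner, MultitaskEnsemble
from .psmiles import PSMILESError, validate

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "read_psmiles_file", "write_psmiles_file",
           "read_property_csv", "write_property_csv",
           "save_predictor", "load_predictor"]

_CSV_HEADER = ["psmiles_1", "psmiles_2", "c_1", "c_2", "property", "value"]


@dataclasses.dataclass
class RunConfig:
    """Resolved parameters of one CLI run, serialized for provenance."""

    seed: int = 0
    command: str = ""
    params: dict = dataclasses.field(default_factory=dict)
    verbosity: str = "INFO"

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)

    @classmethod
    def load(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def read_psmiles_file(path: str) -> list[str]:
    """One PSMILES per non-comment line; raises listing every bad line."""
    out: list[str] = []
    bad: list[tuple[int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            rep = validate(text)
            if rep.valid:
                out.append(text)
            else:
                bad.append((lineno, ", ".join(rep.issues)))
    if bad:
        detail = "; ".join(f"line {n}: {msg}" for n, msg in bad)
        raise PSMILESError(f"{path}: invalid PSMILES ({detail})")
    return out


def write_psmiles_file(polymers: list[str], path: str) -> None:
    with open(path, "w") as fh:
        for p in polymers:
            fh.write(p + "\n")


def read_property_csv(path: str) -> list[PolymerRecord]:
    """Read the property-table schema into records.

    Homopolymer rows leave ``psmiles_2``/``c_2`` blank (``c_1`` then
    defaults to 1); copolymer fractions must sum to 1.
    """
    records: list[PolymerRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != _CSV_HEADER:
            raise ValueError(f"{path}: expected header {','.join(_CSV_HEADER)}")
        for lineno, row in enumerate(reader, start=2):
            symbol = row["property"].strip()
            if symbol not in REGISTRY:
                raise KeyError(f"{path} line {lineno}: unregistered property {symbol!r}")
            p1 = row["psmiles_1"].strip()
            p2 = row["psmiles_2"].strip()
            c1 = float(row["c_1"]) if row["c_1"].strip() else 1.0
            if p2:
                c2 = float(row["c_2"]) if row["c_2"].strip() else 1.0 - c1
                comonomers = ((p1, c1), (p2, c2))
            else:
                comonomers = ((p1, c1),)
            try:
                records.append(PolymerRecord(comonomers, symbol,
                                             float(row["value"])))
            except ValueError as exc:
                raise ValueError(f"{path} line {lineno}: {exc}") from exc
    return records


def write_property_csv(records: list[PolymerRecord], path: str) -> None:
    """Inverse of :func:`read_property_csv` up to float formatting."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_HEADER)
        for r in records:
            p1, c1 = r.comonomers[0]
            if len(r.comonomers) > 1:
                p2, c2 = r.comonomers[1]
                writer.writerow([p1, p2, repr(c1), repr(c2), r.symbol,
                                 repr(r.value)])
            else:
                writer.writerow([p1, "", repr(c1), "", r.symbol, repr(r.value)])


def save_predictor(ensemble: MultitaskEnsemble, meta: MetaLearner,
                   path: str, extra: dict | None = None) -> None:
    """Persist the CV ensemble + meta learner to a run directory."""
    os.makedirs(path, exist_ok=True)
    joblib.dump({"ensemble": ensemble, "meta": meta}, os.path.join(path, "predictor.joblib"))
    with open(os.path.join(path, "predictor.json"), "w") as fh:
        json.dump({"symbols": list(ensemble.symbols),
                   "fold_val_r2": ensemble.fold_val_r2,
                   "meta_validation_r2": meta.validation_r2,
                   **(extra or {})}, fh, indent=2)


def load_predictor(path: str) -> tuple[MultitaskEnsemble, MetaLearner]:
    f = os.path.join(path, "predictor.joblib")
    if not os.path.exists(f):
        raise FileNotFoundError(f"no predictor at {path}")
    blob = joblib.load(f)
    return blob["ensemble"], blob["meta"]
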