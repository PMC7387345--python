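"""Run configuration, output writing and provenance.

A run configuration is a small declarative document (JSON or YAML) naming
the phenotype, the protocol (catalog name or inline fields), the engine and
the seeds.  Every run emits a provenance block sufficient to reproduce it
bit-for-bit; numeric outputs are written with full precision (repr round
trip).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .network import PHENOTYPES, CellPhenotype
from .protocols import Protocol, get_protocol, make_protocol, protocol_catalog

__all__ = ["RunConfig", "ConfigError", "load_config", "write_outputs"]


class ConfigError(ValueError):
    """Invalid or unknown configuration key/value."""


_ENGINES = ("ode", "ssa", "ssa-exact")

_PROTOCOL_KEYS = {"name", "cycle_h", "n_cycles", "ir_dose_per_day",
                  "inhibitor"}
_INHIBITOR_KEYS = {"mode", "dose", "offsets_h"}
_PHENOTYPE_KEYS = {"label", "s1_multiplier", "s2_multiplier",
                   "uptake_specificity"}
_TOP_KEYS = {"protocol", "phenotype", "engine", "seed", "n_cells",
             "horizon_h", "sample_every_h", "ir_crit_tolerance", "outdir",
             "network_tsv"}


@dataclass(frozen=True)
class RunConfig:
    """Fully validated, default-materialized run description."""

    protocol: Protocol
    phenotype: CellPhenotype
    engine: str = "ode"
    seed: int = 0
    n_cells: int = 100
    horizon_h: float | None = None
    sample_every_h: float = 0.1
    ir_crit_tolerance: float = 0.01
    outdir: str = "results"
    network_tsv: str | None = None

    def provenance(self) -> dict:
        """A JSON-serializable block from which the run can be rebuilt."""
        prot = dataclasses.asdict(self.protocol)
        phen = dataclasses.asdict(self.phenotype)
        return {
            "p53combo_version": __version__,
            "protocol": prot,
            "phenotype": phen,
            "engine": self.engine,
            "seed": self.seed,
            "n_cells": self.n_cells,
            "horizon_h": self.horizon_h,
            "sample_every_h": self.sample_every_h,
            "ir_crit_tolerance": self.ir_crit_tolerance,
            "outdir": self.outdir,
            "network_tsv": self.network_tsv,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        unknown = set(doc) - _TOP_KEYS - {"p53combo_version"}
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
        if "protocol" not in doc:
            raise ConfigError("missing required key 'protocol'")
        protocol = _parse_protocol(doc["protocol"])
        phenotype = _parse_phenotype(doc.get("phenotype", "normal"))
        engine = doc.get("engine", "ode")
        if engine not in _ENGINES:
            raise ConfigError(f"unknown engine '{engine}' (one of {_ENGINES})")
        return cls(
            protocol=protocol,
            phenotype=phenotype,
            engine=engine,
            seed=int(doc.get("seed", 0)),
            n_cells=int(doc.get("n_cells", 100)),
            horizon_h=doc.get("horizon_h"),
            sample_every_h=float(doc.get("sample_every_h", 0.1)),
            ir_crit_tolerance=float(doc.get("ir_crit_tolerance", 0.01)),
            outdir=str(doc.get("outdir", "results")),
            network_tsv=doc.get("network_tsv"),
        )


def _parse_protocol(doc) -> Protocol:
    if isinstance(doc, str):
        return get_protocol(doc)
    if not isinstance(doc, dict):
        raise ConfigError("'protocol' must be a catalog name or a mapping")
    unknown = set(doc) - _PROTOCOL_KEYS
    if unknown:
        raise ConfigError(f"unknown protocol key(s): {sorted(unknown)}")
    if "name" in doc and "cycle_h" not in doc:
        base = get_protocol(doc["name"])
        if "ir_dose_per_day" in doc:
            base = base.with_ir_dose(doc["ir_dose_per_day"])
        return base
    inh = doc.get("inhibitor", {}) or {}
    unknown = set(inh) - _INHIBITOR_KEYS
    if unknown:
        raise ConfigError(f"unknown inhibitor key(s): {sorted(unknown)}")
    try:
        return make_protocol(
            cycle_h=int(doc["cycle_h"]),
            n_cycles=int(doc["n_cycles"]),
            ir_dose_per_day=doc.get("ir_dose_per_day"),
            offsets=tuple(inh.get("offsets_h", ())),
            inh_dose=float(inh.get("dose", 0.0)),
            mode=inh.get("mode", "none"),
            name=doc.get("name", ""),
        )
    except KeyError as e:
        raise ConfigError(f"missing protocol key {e}") from None


def _parse_phenotype(doc) -> CellPhenotype:
    if isinstance(doc, str):
        try:
            return PHENOTYPES[doc]
        except KeyError:
            raise ConfigError(
                f"unknown phenotype '{doc}' (one of {sorted(PHENOTYPES)})"
            ) from None
    if not isinstance(doc, dict):
        raise ConfigError("'phenotype' must be a label or a mapping")
    unknown = set(doc) - _PHENOTYPE_KEYS
    if unknown:
        raise ConfigError(f"unknown phenotype key(s): {sorted(unknown)}")
    try:
        return CellPhenotype(
            label=doc.get("label", "custom"),
            s1_multiplier=float(doc.get("s1_multiplier", 1.0)),
            s2_multiplier=float(doc.get("s2_multiplier", 1.0)),
            uptake_specificity=float(doc.get("uptake_specificity", 1.0)),
        )
    except ValueError as e:
        raise ConfigError(str(e)) from None


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON/YAML run configuration.

    Unknown keys are rejected with a message naming the offending key; the
    returned config has every default materialized, so re-emitting its
    provenance and re-loading gives an identical configuration.
    """
    path = Path(path)
    text = path.read_text()
    doc = yaml.safe_load(text)  # YAML is a superset of JSON
    if not isinstance(doc, dict):
        raise ConfigError("configuration must be a mapping")
    return RunConfig.from_dict(doc)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_outputs(results: dict, outdir: str | Path,
                  provenance: dict | None = None) -> dict:
    """Write result objects and a manifest.

    ``results`` maps file names to payloads: pandas DataFrames become
    CSV/TSV (by extension), dicts/lists become JSON, strings are written
    verbatim.  A ``provenance.json`` and a ``manifest.json`` (names +
    sha256 checksums) are always produced; the manifest is returned.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, payload in results.items():
        p = outdir / name
        if hasattr(payload, "to_csv"):
            sep = "\t" if p.suffix == ".tsv" else ","
            payload.to_csv(p, sep=sep, index=False)  # repr: shortest exact
        elif isinstance(payload, (dict, list)):
            p.write_text(json.dumps(payload, indent=2, default=_json_default)
                         + "\n")
        elif isinstance(payload, str):
            p.write_text(payload)
        else:
            raise ConfigError(f"cannot serialize payload for '{name}'")
        written.append(p)
    prov = outdir / "provenance.json"
    prov.write_text(json.dumps(provenance or {}, indent=2,
                               default=_json_default) + "\n")
    written.append(prov)
    manifest = {
        "files": [
            {"name": p.name, "sha256": _sha256(p)} for p in sorted(written)
        ]
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _json_default(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")
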