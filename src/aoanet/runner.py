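"""End-to-end experiment runs: config parsing, seeding policy, provenance.

A single YAML config drives a whole experiment: generate (or load) a
lexicon, train under one of the simulation protocols, optionally lesion the
trained network, analyze, and write all CSV/JSON outputs plus a run
manifest.  One master seed spawns independent child streams for lexicon
generation, weight initialisation and presentation shuffling; every derived
seed is recorded in the manifest, and no step reads the clock or any
unseeded randomness, so re-running a config reproduces every output
byte-identically.

Config schema (all keys optional unless noted)::

    seed: 7                     # master seed (required)
    out_dir: out                # output directory (required for run())
    protocol: sim1              # sim1..sim7
    lexicon:
      path: lexicon.csv         # load instead of generating
      group_sizes: {1: 82, 2: 62, 3: 56, 4: 49, 5: 78}
      n_letters: 33
      n_phonemes: 28
      mapping_mode: quasi_regular   # or arbitrary
      inconsistency_rate: 0.2
    overrides:                  # desk-scale protocol overrides
      n_early: 20
      n_late: 20
      epochs: [50, 50]
      eval_every: 10
    network:
      n_hidden: 100
      init_range: 0.5
    lesion:                     # presence enables the lesion experiment
      severities: [0.05, 0.10, 0.20]
      methods: [zero_weights, add_noise]
      n_samples: 20
      noise_sd: 0.5
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from . import __version__
from .curriculum import SIM_IDS, TrainingRecord, build_protocol, run_protocol
from .lesion import METHODS, run_lesion_experiment
from .lexicon import (
    DEFAULT_GROUP_SIZES,
    DEFAULT_N_LETTERS,
    DEFAULT_N_PHONEMES,
    Lexicon,
    LexiconConfig,
    generate_lexicon,
)
from .metrics import ancova, group_summary
from .network import init_network

import numpy as np


class ConfigError(ValueError):
    """Invalid experiment configuration; the message names the offending key."""


def _require(cond: bool, key: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"config key '{key}': {msg}")


def validate_config(cfg: dict) -> dict:
    """Validate and expand a config dict to its fully resolved form."""
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    out: dict = {}
    _require("seed" in cfg, "seed", "is required")
    _require(isinstance(cfg["seed"], int) and cfg["seed"] >= 0, "seed", "must be a nonnegative integer")
    out["seed"] = cfg["seed"]
    out["protocol"] = cfg.get("protocol", "sim1")
    _require(out["protocol"] in SIM_IDS, "protocol", f"must be one of {SIM_IDS}")

    lex = dict(cfg.get("lexicon") or {})
    lex.setdefault("path", None)
    lex.setdefault("group_sizes", dict(DEFAULT_GROUP_SIZES))
    lex.setdefault("n_letters", DEFAULT_N_LETTERS)
    lex.setdefault("n_phonemes", DEFAULT_N_PHONEMES)
    lex.setdefault("mapping_mode", "quasi_regular")
    lex.setdefault("inconsistency_rate", 0.2)
    _require(
        lex["mapping_mode"] in ("quasi_regular", "arbitrary"),
        "lexicon.mapping_mode",
        "must be quasi_regular or arbitrary",
    )
    _require(
        0.0 <= float(lex["inconsistency_rate"]) <= 1.0,
        "lexicon.inconsistency_rate",
        "must lie in [0, 1]",
    )
    lex["group_sizes"] = {int(k): int(v) for k, v in lex["group_sizes"].items()}
    out["lexicon"] = lex

    ov = dict(cfg.get("overrides") or {})
    if "epochs" in ov:
        ov["epochs"] = tuple(int(e) for e in ov["epochs"])
    out["overrides"] = ov

    net = dict(cfg.get("network") or {})
    net.setdefault("n_hidden", 100)
    net.setdefault("init_range", 0.5)
    _require(int(net["n_hidden"]) >= 1, "network.n_hidden", "must be >= 1")
    out["network"] = net

    les = cfg.get("lesion")
    if les is not None:
        les = dict(les)
        les.setdefault("severities", [0.05, 0.10, 0.20])
        les.setdefault("methods", list(METHODS))
        les.setdefault("n_samples", 20)
        les.setdefault("noise_sd", 0.5)
        for s in les["severities"]:
            _require(0.0 <= float(s) <= 1.0, "lesion.severity", f"value {s} must lie in [0, 1]")
        for m in les["methods"]:
            _require(m in METHODS, "lesion.methods", f"unknown method {m!r}")
        _require(int(les["n_samples"]) >= 1, "lesion.n_samples", "must be >= 1")
    out["lesion"] = les
    return out


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return validate_config(cfg or {})


def child_seeds(master_seed: int, n: int = 4) -> List[int]:
    """Derive independent child seeds (< 2^31) from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


@dataclass
class RunManifest:
    """Provenance of one run: resolved config, seeds, inputs, outputs."""

    config: dict
    master_seed: int
    stream_seeds: Dict[str, int]
    version: str = __version__
    input_digests: Dict[str, str] = field(default_factory=dict)
    outputs: List[str] = field(default_factory=list)

    def save(self, path) -> None:
        doc = {
            "version": self.version,
            "master_seed": self.master_seed,
            "stream_seeds": self.stream_seeds,
            "config": _jsonable(self.config),
            "input_digests": self.input_digests,
            "outputs": self.outputs,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def resolve_lexicon(cfg: dict, seed: int) -> tuple[Lexicon, Optional[str]]:
    """Load the configured lexicon CSV or generate one from the config."""
    lex_cfg = cfg["lexicon"]
    if lex_cfg["path"]:
        path = lex_cfg["path"]
        if not Path(path).exists():
            raise ConfigError(f"config key 'lexicon.path': file not found: {path}")
        return (
            Lexicon.from_csv(path, n_letters=lex_cfg["n_letters"], n_phonemes=lex_cfg["n_phonemes"]),
            path,
        )
    gen = LexiconConfig(
        group_sizes=lex_cfg["group_sizes"],
        n_letters=lex_cfg["n_letters"],
        n_phonemes=lex_cfg["n_phonemes"],
        mapping_mode=lex_cfg["mapping_mode"],
        inconsistency_rate=float(lex_cfg["inconsistency_rate"]),
        seed=seed,
    )
    return generate_lexicon(gen), None


def run(config_path, out_dir: Optional[str] = None) -> RunManifest:
    """Execute generate -> train -> (lesion) -> analyze and write all outputs."""
    raw = yaml.safe_load(open(config_path)) or {}
    cfg = validate_config(raw)
    out = Path(out_dir or raw.get("out_dir") or ".")
    out.mkdir(parents=True, exist_ok=True)

    seeds = child_seeds(cfg["seed"], 4)
    stream_seeds = {
        "lexicon": seeds[0],
        "network_init": seeds[1],
        "shuffle": seeds[2],
        "lesion": seeds[3],
    }
    manifest = RunManifest(config=cfg, master_seed=cfg["seed"], stream_seeds=stream_seeds)

    lexicon, lex_path = resolve_lexicon(cfg, stream_seeds["lexicon"])
    if lex_path:
        manifest.input_digests[str(lex_path)] = _sha256(lex_path)

    def write(name: str, writer) -> Path:
        path = out / name
        writer(path)
        manifest.outputs.append(name)
        return path

    write("lexicon.csv", lexicon.to_csv)

    protocol = build_protocol(
        cfg["protocol"], lexicon, overrides=cfg["overrides"], seed=stream_seeds["shuffle"]
    )
    net0 = init_network(
        n_in=4 * lexicon.n_letters,
        n_hidden=int(cfg["network"]["n_hidden"]),
        n_out=4 * lexicon.n_phonemes,
        init_range=float(cfg["network"]["init_range"]),
        seed=stream_seeds["network_init"],
    )
    record: TrainingRecord = run_protocol(protocol, net0, lexicon)

    write("trajectory.csv", lambda p: record.trajectory.to_csv(p, index=False))
    write("network.json", record.final_state.save)
    final = record.final_results()
    write("results.csv", lambda p: final.to_csv(p, index=False))
    write("group_summary.csv", lambda p: group_summary(final).to_csv(p, index=False))

    analysis = {
        "protocol": cfg["protocol"],
        "first_trained_advantage": record.first_trained_advantage(),
        "notes": record.metadata["notes"],
        "total_presentations": record.metadata["total_presentations"],
    }
    # the covariance analysis needs every factor level populated
    if final["grade"].nunique() >= 2 and len(final) > final["grade"].nunique() + 3:
        tab = ancova(final, error_col="sse")
        write("ancova.csv", lambda p: tab.table.to_csv(p, index=False))
        analysis["ancova_trend_F"] = tab.trend_F
        analysis["ancova_trend_p"] = tab.trend_p
    write(
        "analysis.json",
        lambda p: Path(p).write_text(json.dumps(_jsonable(analysis), indent=2, sort_keys=True)),
    )

    if cfg["lesion"] is not None:
        les = cfg["lesion"]
        result = run_lesion_experiment(
            record.final_state,
            lexicon,
            early_ids=protocol.first_trained_ids,
            late_ids=protocol.second_trained_ids,
            severities=[float(s) for s in les["severities"]],
            methods=les["methods"],
            n_samples=int(les["n_samples"]),
            noise_sd=float(les["noise_sd"]),
            seed=stream_seeds["lesion"],
        )
        write("lesion_items.csv", lambda p: result.per_item.to_csv(p, index=False))
        write("lesion_summary.csv", lambda p: result.summary.to_csv(p, index=False))

    write("manifest.json", manifest.save)
    return manifest
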