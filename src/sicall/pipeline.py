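"""End-to-end orchestration: annotate -> count -> quantify -> diff -> join.

Every stage reads and writes plain-text TSV/JSON so intermediates are
independently inspectable; a manifest records the tool version, a config
hash, input digests and per-stage row counts.  Re-running with identical
inputs and config reproduces identical result files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Union

import yaml

from . import __version__
from .annotation import enumerate_events, parse_gtf, write_events
from .differential import (
    Thresholds,
    call_contrast,
    join_bidirectional,
    write_contrast_results,
    write_high_confidence_calls,
)
from .junctions import (
    JunctionCountTable,
    ReadFilters,
    SpliceSiteIndex,
    count_sample,
    read_sj_table,
    write_count_table,
)
from .quantify import quantify_all, write_quantifications

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path: Union[str, Path]) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def validate_config(config: dict) -> None:
    """Fail fast, naming the missing piece, before any stage runs."""
    for key in ("annotation", "samples", "contrasts"):
        if key not in config:
            raise ConfigError(f"config missing required key '{key}'")
    if not Path(config["annotation"]).exists():
        raise ConfigError(f"annotation file not found: {config['annotation']}")
    for sample_id, spec in config["samples"].items():
        if not isinstance(spec, dict) or not ({"sj", "sam"} & set(spec)):
            raise ConfigError(
                f"sample '{sample_id}' must name an 'sj' or 'sam' input"
            )
        src = spec.get("sj") or spec.get("sam")
        if not Path(src).exists():
            raise ConfigError(f"sample '{sample_id}': input not found: {src}")
    sample_ids = set(config["samples"])
    for con in config["contrasts"]:
        for key in ("id", "kind", "treatment", "control"):
            if key not in con:
                raise ConfigError(
                    f"contrast {con.get('id', '?')} missing '{key}'"
                )
        if con["kind"] not in ("KD", "OE"):
            raise ConfigError(
                f"contrast {con['id']}: kind must be KD or OE"
            )
        for arm in ("treatment", "control"):
            missing = set(con[arm]) - sample_ids
            if missing:
                raise ConfigError(
                    f"contrast {con['id']}: unknown {arm} samples {sorted(missing)}"
                )


def run_pipeline(
    config: Union[dict, str, Path], outdir: Union[str, Path]
) -> dict[str, Any]:
    """Execute the pipeline per config; returns the manifest."""
    if not isinstance(config, dict):
        config = load_config(config)
    validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict[str, Any] = {
        "tool": "sicall",
        "version": __version__,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "inputs": {},
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    manifest["inputs"]["annotation"] = _digest(Path(config["annotation"]))

    models = parse_gtf(config["annotation"])
    events = enumerate_events(models)
    write_events(events, outdir / "events.tsv")
    manifest["stages"]["annotate"] = {
        "transcripts": len(models),
        "events": len(events),
    }
    logger.info("annotate: %d transcripts -> %d events", len(models), len(events))

    index = SpliceSiteIndex(models)
    filters = ReadFilters(**config.get("read_filters", {}))
    tables: dict[str, JunctionCountTable] = {}
    for sample_id, spec in config["samples"].items():
        src = Path(spec.get("sj") or spec.get("sam"))
        manifest["inputs"][sample_id] = _digest(src)
        if "sj" in spec:
            tables[sample_id] = read_sj_table(src, index, sample_id=sample_id)
        else:
            tables[sample_id] = count_sample(
                src, index, filters, sample_id=sample_id
            )
        write_count_table(tables[sample_id], outdir / f"counts.{sample_id}.tsv")
    manifest["stages"]["count"] = {
        s: sum(t.junction_counts.values()) for s, t in tables.items()
    }

    combiner = config.get("si_combiner", "mean")
    quants = {
        s: quantify_all(events, t, combiner) for s, t in tables.items()
    }
    for s, q in quants.items():
        write_quantifications(
            sorted(q.values(), key=lambda x: x.event_id),
            outdir / f"quant.{s}.tsv",
        )
    manifest["stages"]["quantify"] = {"events": len(events), "samples": len(quants)}

    thresholds = Thresholds(**config.get("thresholds", {}))
    kd_results, oe_results = [], []
    for con in config["contrasts"]:
        res = call_contrast(
            [quants[s] for s in con["treatment"]],
            [quants[s] for s in con["control"]],
            contrast_id=con["id"],
            thresholds=thresholds,
        )
        write_contrast_results(res, outdir / f"diff.{con['id']}.tsv")
        (kd_results if con["kind"] == "KD" else oe_results).append(res)
        manifest["stages"][f"diff.{con['id']}"] = {
            "tested": int(sum(r.tested for r in res)),
            "passing": int(sum(bool(r.passes_filters) for r in res)),
        }

    mode = config.get("mode", "strict")
    calls = join_bidirectional(kd_results, oe_results, mode=mode)
    write_high_confidence_calls(calls, outdir / "high_confidence_calls.tsv")
    manifest["stages"]["join"] = {"mode": mode, "calls": len(calls)}
    logger.info("join: %d high-confidence calls (%s mode)", len(calls), mode)

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
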