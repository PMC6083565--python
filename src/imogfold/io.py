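"""Configuration files, result serialisation, and batch reports.

Every result file embeds a manifest (config snapshot, package version,
timestamp, input checksum, seeds) so a fold can be traced back to the exact
run that produced it, and every format written here is re-parsable by the
package itself.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .imo import IMOConfig
from .sequences import HPSequence
from .solver import BatchStats, RunResult


def load_config(path: str | Path | None) -> IMOConfig:
    """Load an :class:`IMOConfig` from YAML/JSON; missing fields take defaults."""
    if path is None:
        return IMOConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return IMOConfig.from_dict(data)


def save_config(config: IMOConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def make_manifest(seq: HPSequence, config: IMOConfig, seeds: list[int]) -> dict:
    return {
        "package": f"imogfold {__version__}",
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "input_sha256": hashlib.sha256(str(seq).encode()).hexdigest(),
        "config": config.to_dict(),
        "seeds": seeds,
    }


def run_result_to_json(result: RunResult, config: IMOConfig) -> str:
    doc = result.to_dict()
    doc["manifest"] = make_manifest(result.sequence, config, [result.seed])
    return json.dumps(doc, indent=2)


def batch_to_json(stats: BatchStats) -> str:
    doc = {
        "label": stats.sequence.label,
        "sequence": str(stats.sequence),
        "runs": stats.runs,
        "best": stats.best,
        "mean": None if stats.mean is None else round(stats.mean, 2),
        "per_run": [r.to_dict() for r in stats.per_run],
        "manifest": make_manifest(
            stats.sequence, stats.config, [r.seed for r in stats.per_run]
        ),
    }
    return json.dumps(doc, indent=2)


def batch_to_frame(batches: list[BatchStats]) -> pd.DataFrame:
    """Best/Mean summary table over sequences (energies as integers, means 2 dp)."""
    rows = []
    for b in batches:
        rows.append(
            {
                "label": b.sequence.label,
                "length": b.sequence.n,
                "runs": b.runs,
                "best": b.best,
                "mean": None if b.mean is None else round(b.mean, 2),
            }
        )
    return pd.DataFrame(rows)


def batch_to_tsv(batches: list[BatchStats]) -> str:
    return batch_to_frame(batches).to_csv(sep="\t", index=False)


def embedding_to_tsv(result: RunResult) -> str:
    """1-based (index, q, r, residue) rows for the best embedding."""
    lines = ["index\tq\tr\tresidue"]
    assert result.best_embedding is not None
    for i, ((q, r), res) in enumerate(
        zip(result.best_embedding, result.sequence.residues), start=1
    ):
        lines.append(f"{i}\t{q}\t{r}\t{res}")
    return "\n".join(lines) + "\n"
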