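"""File readers/writers and run configuration.

Gene sets arrive as GMT (tab-delimited: id, description, genes; the
description is mapped to the ground-truth name when present) or as a CSV
dialect with one set per row: id, optional ground-truth name, then the
comma-separated gene symbols.  Results are written as JSON files so the
call log and both verification reports stay paired with the outputs.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, ConfigDict

from .types import GeneSet, GeneSetError, PipelineResult, SetSource, validate_gene_set

logger = logging.getLogger(__name__)


class RunConfig(BaseModel):
    """Run-wide configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    backend: str = "scripted"
    transcript_path: Optional[str] = None
    kb_dir: Optional[str] = None
    encoder: str = "toy"
    temperature: float = 0.0
    cache_dir: Optional[str] = None
    log_level: str = "INFO"
    output_path: Optional[str] = None


def read_gene_sets(
    path: str | Path,
    fmt: str = "gmt",
    source: SetSource = SetSource.custom,
) -> list[GeneSet]:
    """Read gene sets from a GMT or one-set-per-row CSV file.

    Ragged or empty rows are skipped with a per-row warning and a final
    summary count; valid rows always parse.
    """
    path = Path(path)
    rows: list[dict] = []
    skipped = 0
    if fmt == "gmt":
        for ln, line in enumerate(path.read_text().splitlines(), 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                logger.warning("%s:%d: ragged GMT row skipped", path.name, ln)
                skipped += 1
                continue
            desc = parts[1].strip()
            rows.append(
                {
                    "id": parts[0],
                    "ground_truth": desc or None,
                    "genes": parts[2:],
                }
            )
    elif fmt == "csv":
        with path.open(newline="") as fh:
            for ln, parts in enumerate(csv.reader(fh), 1):
                if not parts or not any(p.strip() for p in parts):
                    continue
                if len(parts) < 2:
                    logger.warning("%s:%d: ragged CSV row skipped", path.name, ln)
                    skipped += 1
                    continue
                # id, optional ground truth, genes...; a 2-column row has
                # no ground truth.
                if len(parts) == 2:
                    gt, genes = None, parts[1:]
                else:
                    gt, genes = parts[1].strip() or None, parts[2:]
                rows.append({"id": parts[0], "ground_truth": gt, "genes": genes})
    else:
        raise ValueError(f"unknown gene-set format {fmt!r}")

    sets: list[GeneSet] = []
    for row in rows:
        row["source"] = source
        try:
            sets.append(validate_gene_set(row))
        except GeneSetError as exc:
            logger.warning("%s: %s — row skipped", path.name, exc)
            skipped += 1
    if skipped:
        logger.warning("%s: %d row(s) skipped", path.name, skipped)
    return sets


def write_gene_sets_gmt(sets: list[GeneSet], path: str | Path) -> None:
    lines = [
        "\t".join([gs.set_id, gs.ground_truth or "", *gs.genes]) for gs in sets
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_report(result: PipelineResult, path: str | Path) -> None:
    """Serialize a full pipeline trace as JSON with stable key order."""
    path = Path(path)
    try:
        path.write_text(result.to_json())
    except OSError as exc:
        raise IOError(f"cannot write report to {path}: {exc}") from exc


def read_report(path: str | Path) -> PipelineResult:
    return PipelineResult.model_validate(json.loads(Path(path).read_text()))


def read_background(path: str | Path) -> list[str]:
    return [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip()
    ]
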