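"""Tabular I/O: TSV dialects for counts, annotations, traces and curves.

All tabular files are tab-separated with a header row, UTF-8, '.' decimal.
Assay traces and growth curves may carry ``# key=value`` metadata lines
before the header. JSON reports get a provenance header (tool version,
seed, config hash).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .assays import AssayTrace, GrowthCurve
from .deg import CountMatrix

__all__ = [
    "read_counts_tsv",
    "write_counts_tsv",
    "read_conditions_tsv",
    "read_annotation_tsv",
    "read_trace_tsv",
    "write_trace_tsv",
    "read_growth_tsv",
    "write_growth_tsv",
    "write_json_report",
]


def _read_metadata(path: Path) -> tuple[dict[str, str], int]:
    meta: dict[str, str] = {}
    skip = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta, skip


def read_counts_tsv(counts_path: str | Path, conditions_path: str | Path) -> CountMatrix:
    """Read a gene_id + per-sample counts TSV and a (sample, condition) map TSV."""
    table = pd.read_csv(counts_path, sep="\t", comment="#")
    if table.columns[0] != "gene_id":
        raise ValueError(f"first column of {counts_path} must be 'gene_id'")
    conditions = read_conditions_tsv(conditions_path)
    samples = list(table.columns[1:])
    missing = [s for s in samples if s not in conditions]
    if missing:
        raise ValueError(f"samples without condition label: {missing}")
    return CountMatrix(
        gene_ids=table["gene_id"].tolist(),
        counts=table[samples].to_numpy(),
        condition=[conditions[s] for s in samples],
    )


def write_counts_tsv(m: CountMatrix, counts_path: str | Path, conditions_path: str | Path) -> None:
    samples = [f"sample_{i+1:02d}" for i in range(len(m.condition))]
    table = pd.DataFrame(m.counts, columns=samples)
    table.insert(0, "gene_id", list(m.gene_ids))
    table.to_csv(counts_path, sep="\t", index=False)
    pd.DataFrame({"sample": samples, "condition": list(m.condition)}).to_csv(
        conditions_path, sep="\t", index=False
    )


def read_conditions_tsv(path: str | Path) -> dict[str, str]:
    table = pd.read_csv(path, sep="\t", comment="#")
    for col in ("sample", "condition"):
        if col not in table.columns:
            raise ValueError(f"{path} must have columns 'sample' and 'condition'")
    return dict(zip(table["sample"], table["condition"]))


def read_annotation_tsv(path: str | Path) -> dict[str, list[str]]:
    """gene_id -> list of categories (one row per gene/category pair)."""
    table = pd.read_csv(path, sep="\t", comment="#")
    for col in ("gene_id", "category"):
        if col not in table.columns:
            raise ValueError(f"{path} must have columns 'gene_id' and 'category'")
    annotation: dict[str, list[str]] = {}
    for gene, cat in zip(table["gene_id"], table["category"]):
        annotation.setdefault(gene, []).append(cat)
    return annotation


_TRACE_META = ("epsilon_mM_cm", "path_cm", "volume_ml", "protein_mg", "electrons_per_chromophore")


def read_trace_tsv(path: str | Path) -> AssayTrace:
    """(time_min, absorbance) TSV with assay constants in '# key=value' header lines."""
    path = Path(path)
    meta, _ = _read_metadata(path)
    missing = [k for k in _TRACE_META if k not in meta]
    if missing:
        raise ValueError(f"{path} is missing metadata line(s): {missing}")
    table = pd.read_csv(path, sep="\t", comment="#")
    return AssayTrace(
        times_min=table["time_min"].to_numpy(),
        absorbance=table["absorbance"].to_numpy(),
        epsilon_mM_cm=float(meta["epsilon_mM_cm"]),
        path_cm=float(meta["path_cm"]),
        volume_ml=float(meta["volume_ml"]),
        protein_mg=float(meta["protein_mg"]),
        electrons_per_chromophore=int(meta["electrons_per_chromophore"]),
    )


def write_trace_tsv(trace: AssayTrace, path: str | Path, seed: int | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# tool=acetoledger {__version__}\n")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        fh.write(f"# epsilon_mM_cm={trace.epsilon_mM_cm}\n")
        fh.write(f"# path_cm={trace.path_cm}\n")
        fh.write(f"# volume_ml={trace.volume_ml}\n")
        fh.write(f"# protein_mg={trace.protein_mg}\n")
        fh.write(f"# electrons_per_chromophore={trace.electrons_per_chromophore}\n")
        pd.DataFrame({"time_min": trace.times_min, "absorbance": trace.absorbance}).to_csv(
            fh, sep="\t", index=False
        )


def read_growth_tsv(path: str | Path) -> GrowthCurve:
    table = pd.read_csv(path, sep="\t", comment="#")
    return GrowthCurve(times_h=table["time_h"].to_numpy(), od600=table["od600"].to_numpy())


def write_growth_tsv(curve: GrowthCurve, path: str | Path, seed: int | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# tool=acetoledger {__version__}\n")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        pd.DataFrame({"time_h": curve.times_h, "od600": curve.od600}).to_csv(
            fh, sep="\t", index=False
        )


def write_json_report(payload: Mapping, path: str | Path, seed: int | None = None) -> None:
    """JSON report with a provenance block (tool version, seed, payload hash)."""
    body = json.dumps(payload, indent=2, sort_keys=True, default=_json_default)
    provenance = {
        "tool": "acetoledger",
        "version": __version__,
        "seed": seed,
        "config_hash": hashlib.sha256(body.encode()).hexdigest()[:16],
    }
    document = {"provenance": provenance, "report": json.loads(body)}
    Path(path).write_text(json.dumps(document, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
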