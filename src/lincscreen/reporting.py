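"""Screen outputs: audit TSVs, the JSON run record, markdown report.

Every number in the rendered report comes straight from a ScreenResult
field (or from the TSVs written from one) — the renderer recomputes
nothing. Missing values are written as '.'.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .orf import write_orf_tsv
from .promoter import CONDITION_POST, CONDITION_PRE
from .screen import ScreenConfig, ScreenResult

VENN_SEP = "&"


def result_frames(result: ScreenResult, cfg: ScreenConfig) -> dict[str, pd.DataFrame]:
    """The cascade, Venn, candidate and per-call tables as DataFrames."""
    stages = pd.DataFrame(result.stage_counts, columns=["stage", "count"])

    venn = pd.DataFrame(
        [(VENN_SEP.join(region), n) for region, n in result.venn.items()],
        columns=["region", "count"],
    )

    cand_rows = []
    for rank, c in enumerate(result.candidates, start=1):
        row: dict[str, object] = {
            "rank": rank,
            "transcript_id": c.transcript_id,
            "locus_id": c.locus_id,
        }
        for mark in cfg.marks:
            row[f"density_{mark}_{CONDITION_POST}"] = c.post_densities[mark]
        row["tf_overlap_bp"] = c.tf_overlap_bp
        cand_rows.append(row)
    cand_cols = ["rank", "transcript_id", "locus_id"] + [
        f"density_{m}_{CONDITION_POST}" for m in cfg.marks
    ] + ["tf_overlap_bp"]
    candidates = pd.DataFrame(cand_rows, columns=cand_cols)

    calls = pd.DataFrame(
        [
            {
                "transcript_id": call.transcript_id,
                "mark": call.mark,
                "d_pre": call.d_pre,
                "d_post": call.d_post,
                "ratio": call.ratio,
                "increased": call.increased,
            }
            for call in result.calls
        ],
        columns=["transcript_id", "mark", "d_pre", "d_post", "ratio", "increased"],
    )
    return {"stages": stages, "venn": venn, "candidates": candidates, "calls": calls}


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_run_outputs(
    result: ScreenResult,
    cfg: ScreenConfig,
    outdir: str | Path,
    input_paths: Mapping[str, str | Path] | None = None,
    timings: Mapping[str, float] | None = None,
) -> dict[str, Path]:
    """Write stages.tsv, venn.tsv, candidates.tsv, calls.tsv, run.json
    (and orf.tsv when the coding stage ran) into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = result_frames(result, cfg)
    paths: dict[str, Path] = {}
    for name, df in frames.items():
        paths[name] = outdir / f"{name}.tsv"
        df.to_csv(paths[name], sep="\t", index=False, na_rep=".")
    if result.orf_reports:
        paths["orf"] = outdir / "orf.tsv"
        write_orf_tsv(list(result.orf_reports), paths["orf"], cfg.coding_max_orf_aa)

    record = {
        "version": __version__,
        "config": dataclasses.asdict(cfg),
        "inputs": {
            name: {"path": str(p), "sha256": file_digest(p)}
            for name, p in (input_paths or {}).items()
        },
        "stage_counts": [[s, n] for s, n in result.stage_counts],
        "timings_s": dict(timings or {}),
    }
    paths["run"] = outdir / "run.json"
    with open(paths["run"], "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def _md_table(df: pd.DataFrame, float_fmt: str = "{:.4f}") -> str:
    if df.empty:
        return "(none)\n"
    show = df.copy()
    for col in show.columns:
        if show[col].dtype.kind == "f":
            show[col] = show[col].map(float_fmt.format)
    header = "| " + " | ".join(str(c) for c in show.columns) + " |"
    rule = "|" + "|".join(" --- " for _ in show.columns) + "|"
    rows = [
        "| " + " | ".join(str(v) for v in row) + " |"
        for row in show.itertuples(index=False)
    ]
    return "\n".join([header, rule, *rows]) + "\n"


def render_report(
    frames: Mapping[str, pd.DataFrame], top_n: int | None = None
) -> str:
    """Deterministic markdown: cascade table, Venn table, ranked candidates."""
    stages, venn, candidates = frames["stages"], frames["venn"], frames["candidates"]
    lines = ["# lincRNA screen report", "", "## Cascade", ""]
    lines.append(_md_table(stages))
    lines += ["## Venn accounting", ""]
    lines.append(_md_table(venn))
    n_cand = len(candidates)
    if top_n is not None and n_cand > top_n:
        shown = candidates.head(top_n)
        lines += [f"## Candidates (top {top_n} of {n_cand})", ""]
    else:
        shown = candidates
        lines += [f"## Candidates ({n_cand})", ""]
    if n_cand == 0:
        lines.append("No candidates survived the cascade.\n")
    else:
        lines.append(_md_table(shown))
    return "\n".join(lines)


def load_run_dir(rundir: str | Path) -> dict[str, pd.DataFrame]:
    """Reload the audit tables of a finished run; no recomputation."""
    rundir = Path(rundir)
    frames = {}
    for name in ("stages", "venn", "candidates"):
        path = rundir / f"{name}.tsv"
        if not path.exists():
            raise FileNotFoundError(f"{path} missing: not a complete run directory")
        frames[name] = pd.read_csv(path, sep="\t")
    return frames
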