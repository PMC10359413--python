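"""Table readers/writers, run manifests, and the end-to-end pipeline.

Canonical interchange format: sample-major TSV — one row per sample with
``sample``, ``diagnosis`` (RA/OA) and optional ``tissue`` metadata
columns followed by one numeric column per variable.  A variable-major
layout (variables in rows, samples in columns, as in spreadsheet
supplements) is accepted for TSV/CSV/XLSX: the first column holds
variable labels and rows named ``diagnosis``/``tissue`` supply metadata;
failing that, diagnosis is inferred from an RA/OA prefix of the sample ID.
"""

from __future__ import annotations

import hashlib
import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .names import is_fa_label, parse_fa_name
from .profiles import (
    CLOSURE_TOL,
    ProfileMatrix,
    ZMatrix,
    compare_groups,
    compute_derived,
    zscore,
)

__all__ = [
    "read_profile_table",
    "write_profile_table",
    "write_manifest",
    "run_pipeline",
]

META_COLUMNS = ("diagnosis", "tissue")
DIAGNOSES = ("OA", "RA")


class TableError(ValueError):
    pass


def _infer_kind(label: str) -> str:
    if is_fa_label(label):
        return "raw_fa"
    low = label.lower()
    if "ratio" in low:
        return "ratio"
    if "index" in low or "length" in low:
        return "index"
    return "sum"


def _check_numeric(df: pd.DataFrame) -> pd.DataFrame:
    out = df.apply(pd.to_numeric, errors="coerce")
    bad = out.isna() & df.notna()
    if bad.any().any():
        cells = [
            f"(sample {r!r}, variable {c!r})"
            for r in df.index
            for c in df.columns
            if bad.loc[r, c]
        ]
        raise TableError(f"non-numeric cells: {', '.join(cells[:10])}")
    if out.isna().any().any():
        raise TableError("missing values in profile table")
    return out


def read_profile_table(
    path,
    orientation: str | None = None,
    allowed_diagnoses: tuple | None = DIAGNOSES,
    check_closure: bool = True,
    as_z: bool = False,
) -> ProfileMatrix | ZMatrix:
    """Read a profile table from TSV/CSV/XLSX into a ProfileMatrix.

    ``orientation`` is ``"samples"`` (sample-major), ``"variables"``
    (variable-major) or None to auto-detect (XLSX defaults to
    variable-major; text files to sample-major unless the first header
    cell is ``variable``).  ``as_z=True`` reads an already-standardised
    Z-score table (values may be negative; no closure check) and returns
    a :class:`ZMatrix`.
    """
    path = Path(path)
    if not path.exists():
        raise TableError(f"no such file: {path}")
    if path.suffix.lower() in (".xlsx", ".xls"):
        raw = pd.read_excel(path, header=0, index_col=0)
        orientation = orientation or "variables"
    else:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        raw = pd.read_csv(path, sep=sep, header=0, index_col=0)
        if orientation is None:
            first = str(raw.index.name or "").strip().lower()
            orientation = "variables" if first == "variable" else "samples"
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    if orientation == "variables":
        raw = raw.T  # now samples in rows
    raw.index.name = "sample"
    meta_cols = [c for c in raw.columns if c.lower() in META_COLUMNS]
    meta = raw[meta_cols].copy()
    meta.columns = [c.lower() for c in meta_cols]
    values = raw.drop(columns=meta_cols)
    if values.index.duplicated().any():
        dupes = values.index[values.index.duplicated()].tolist()
        raise TableError(f"duplicate sample IDs: {dupes}")
    if "diagnosis" not in meta.columns:
        inferred = [
            next((d for d in DIAGNOSES if str(s).upper().startswith(d)), None)
            for s in values.index
        ]
        if any(d is None for d in inferred):
            raise TableError(
                "no diagnosis metadata and sample IDs do not start with RA/OA"
            )
        meta["diagnosis"] = inferred
    if allowed_diagnoses is not None:
        unknown = set(meta["diagnosis"]) - set(allowed_diagnoses)
        if unknown:
            rows = meta.index[meta["diagnosis"].isin(unknown)].tolist()
            raise TableError(
                f"unknown diagnosis labels {sorted(unknown)} in samples {rows}"
            )
    if "tissue" not in meta.columns:
        meta["tissue"] = "synovium"
    values = _check_numeric(values)
    kind = pd.Series({c: _infer_kind(c) for c in values.columns},
                     name="variable_kind")
    if as_z:
        return ZMatrix(values, meta, kind)
    pm = ProfileMatrix(values, meta, kind)
    if check_closure and len(pm.raw_labels()):
        pm.check_closure(CLOSURE_TOL)
    return pm


def write_profile_table(profiles: ProfileMatrix | ZMatrix, path) -> None:
    """Write the canonical sample-major TSV."""
    path = Path(path)
    meta = profiles.meta[[c for c in META_COLUMNS if c in profiles.meta.columns]]
    out = pd.concat([meta, profiles.values], axis=1).rename_axis("sample")
    out.to_csv(path, sep="\t", float_format="%.10g")


def _file_hash(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_path,
    command: str,
    inputs: list | None = None,
    config: dict | None = None,
    seed=None,
) -> dict:
    """Write a JSON run manifest next to a command's outputs."""
    manifest = {
        "command": command,
        "package_version": __version__,
        "python": platform.python_version(),
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "config": config or {},
        "config_hash": hashlib.sha256(
            json.dumps(config or {}, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "inputs": {str(p): _file_hash(p) for p in (inputs or []) if Path(p).exists()},
    }
    with open(out_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def run_pipeline(config: dict, outdir) -> dict:
    """Run the full analysis on one profile table.

    Stages, in order: derived variables -> per-variable statistics ->
    Z-scores -> FA grouping -> enrichment RF (and a no-enrichment run)
    -> discriminant analysis -> pathway analysis.  All outputs are TSV /
    GraphML / DOT under ``outdir`` plus a run manifest; every stage
    failure aborts with the stage name.
    """
    from . import discriminant, enrichment, grouping, pathway

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.get("seed", 0)
    stage = "read"
    outputs: dict[str, object] = {}
    try:
        if "input" in config:
            pm = read_profile_table(config["input"])
        else:
            pm = config["profiles"]

        stage = "derived"
        if config.get("derived", True):
            pm = compute_derived(pm)

        stage = "stats"
        stats_table = compare_groups(pm, alpha=config.get("alpha", 0.05))
        stats_table.to_csv(outdir / "group_stats.tsv", sep="\t")
        outputs["stats"] = stats_table

        stage = "zscore"
        z = zscore(pm)
        write_profile_table(z, outdir / "zscores.tsv")

        stage = "grouping"
        dendro = grouping.cluster(z, axis="variables")
        groups = grouping.assign_groups(
            dendro, k=config.get("k", 5), manual=config.get("manual_groups")
        )
        groups.rename_axis("variable").to_csv(outdir / "groups.tsv", sep="\t")
        outputs["groups"] = groups

        stage = "rf_enriched"
        enr = enrichment.enrich(
            z, groups, iterations=config.get("iterations", 1000), seed=seed
        )
        run_e = enrichment.train_rf(
            enr.features, enr.labels,
            repeats=config.get("repeats", 100), seed=seed,
        )
        imp_g = enrichment.importance_by_group(run_e)
        imp_g.to_csv(outdir / "rf_group_importance.tsv", sep="\t")
        outputs["rf_enriched"] = run_e

        stage = "rf_full"
        if config.get("no_enrich_run", True):
            run_f = enrichment.train_rf(
                z.values, z.diagnosis,
                repeats=config.get("repeats", 100), seed=seed + 1,
            )
            imp_v = enrichment.importance_by_group(
                run_f, groups, z.variable_kind
            )
            imp_v.rename_axis("variable").to_csv(
                outdir / "rf_variable_importance.tsv", sep="\t"
            )
            outputs["rf_full"] = run_f

        stage = "lda"
        raw = pm.drop_derived()
        lda = discriminant.fit_lda(raw.values, raw.diagnosis)
        scatter = lda.scores.copy()
        if scatter.shape[1] == 1:
            scatter["function_2"] = 0.0
        scatter["class"] = raw.diagnosis
        scatter.rename_axis("sample").to_csv(outdir / "lda_scores.tsv", sep="\t")
        outputs["lda"] = lda

        stage = "pathway"
        # acyl chains only: DMAs (and derived columns) stay out of the network
        acyl = [lab for lab in raw.raw_labels() if not parse_fa_name(lab).is_dma]
        net = pathway.build_network(acyl)
        lc = pathway.level_change(raw, ref=config.get("ref", "OA"),
                                  alt=config.get("alt", "RA"))
        ann = pathway.annotate_edges(net, raw, alpha=config.get("alpha", 0.05),
                                     ref=config.get("ref", "OA"),
                                     alt=config.get("alt", "RA"))
        pathway.export_network(net, ann, lc, prefix=str(outdir / "network"))
        outputs["network"] = net
        outputs["edge_annotations"] = ann
        outputs["level_change"] = lc
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    write_manifest(
        outdir / "manifest.json",
        command="run_pipeline",
        inputs=[config["input"]] if "input" in config else [],
        config={k: v for k, v in config.items()
                if isinstance(v, (str, int, float, bool, type(None)))},
        seed=seed,
    )
    return outputs
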