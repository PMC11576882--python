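"""Tab-separated and JSON readers/writers for every pipeline intermediate."""
from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .datatypes import BiopsyCohort, OmicsMatrix, SampleMeta, SimTruth, samples_to_frame


def write_matrix_tsv(values: pd.DataFrame, path) -> None:
    values.to_csv(path, sep="\t", index_label="feature_id")


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature_id")


def write_samples_tsv(samples: list[SampleMeta], path) -> None:
    samples_to_frame(samples).to_csv(path, sep="\t")


def read_samples_tsv(path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    return [
        SampleMeta(
            sample_id=str(sid),
            cell_type=str(row["cell_type"]),
            condition=str(row["condition"]),
            replicate=int(row["replicate"]),
            batch=str(row["batch"]),
        )
        for sid, row in df.iterrows()
    ]


def write_omics(matrix: OmicsMatrix, prefix: Path) -> list[Path]:
    mat_path = prefix.with_suffix(".tsv")
    meta_path = prefix.parent / (prefix.name + ".samples.tsv")
    write_matrix_tsv(matrix.values, mat_path)
    write_samples_tsv(matrix.samples, meta_path)
    return [mat_path, meta_path]


def read_omics(prefix: Path, layer: str) -> OmicsMatrix:
    values = read_matrix_tsv(prefix.with_suffix(".tsv"))
    samples = read_samples_tsv(prefix.parent / (prefix.name + ".samples.tsv"))
    ids = [s.sample_id for s in samples]
    missing = set(values.columns) ^ set(ids)
    if missing:
        raise ValueError(f"sample metadata does not match matrix columns: {sorted(missing)}")
    return OmicsMatrix(values[ids], samples, layer)


def write_truth_json(truth: SimTruth, path) -> None:
    payload = {
        "shared_genes": sorted(truth.shared_genes),
        "specific_genes": {ct: sorted(g) for ct, g in sorted(truth.specific_genes.items())},
        "planted_log2fc": [
            {"gene": g, "cell_type": ct, "layer": layer, "log2fc": e}
            for (g, ct, layer), e in sorted(truth.planted_log2fc.items())
        ],
        "enriched_sets": sorted(truth.enriched_sets),
        "biopsy_shifted_genes": sorted(truth.biopsy_shifted_genes),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_truth_json(path) -> SimTruth:
    with open(path) as fh:
        payload = json.load(fh)
    return SimTruth(
        shared_genes=set(payload["shared_genes"]),
        specific_genes={ct: set(g) for ct, g in payload["specific_genes"].items()},
        planted_log2fc={
            (d["gene"], d["cell_type"], d["layer"]): d["log2fc"]
            for d in payload["planted_log2fc"]
        },
        enriched_sets=set(payload["enriched_sets"]),
        biopsy_shifted_genes=set(payload["biopsy_shifted_genes"]),
    )


def write_biopsy(cohort: BiopsyCohort, outdir: Path) -> list[Path]:
    expr = outdir / "biopsy_expression.tsv"
    meta = outdir / "biopsy_samples.tsv"
    write_matrix_tsv(cohort.expression, expr)
    table = cohort.phenotypes.copy()
    table.insert(0, "group", cohort.groups)
    table.to_csv(meta, sep="\t", index_label="sample_id")
    return [expr, meta]


def read_biopsy(outdir: Path) -> BiopsyCohort:
    expr = read_matrix_tsv(outdir / "biopsy_expression.tsv")
    meta = pd.read_csv(outdir / "biopsy_samples.tsv", sep="\t", index_col="sample_id")
    groups = meta["group"]
    groups.index = groups.index.astype(str)
    expr.columns = expr.columns.astype(str)
    return BiopsyCohort(
        expression=expr,
        groups=groups,
        phenotypes=meta.drop(columns=["group"]),
    )
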