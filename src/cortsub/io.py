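"""Delimited-text readers/writers, configuration and seeding utilities.

Every artifact is plain TSV or JSON with explicit headers so runs are
inspectable and diff-able.  ROI identity is always matched by column
name (``roi_<id>``), never by position.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import (
    THICKNESS_META_COLUMNS,
    BetaMap,
    ConnectivityTemplate,
    ExpressionMatrix,
    InvalidArgumentError,
    InvalidInputError,
    Parcellation,
    RegionalThicknessTable,
    SubtypeModel,
)

#: fixed stage names for deriving independent random substreams
STAGE_STREAMS = {
    "simulation": 0,
    "subtyping": 1,
    "rewiring": 2,
    "surrogates": 3,
    "genes": 4,
}


def stage_seed(seed: int, stage: str) -> int:
    """Independent per-stage seed derived from the single pipeline seed.

    Stages have fixed stream indices, so consuming more randomness in one
    stage never perturbs another.
    """
    if stage not in STAGE_STREAMS:
        raise InvalidArgumentError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(STAGE_STREAMS[stage],))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


# ---------------------------------------------------------------------------
# thickness table
# ---------------------------------------------------------------------------

def write_thickness(table: RegionalThicknessTable, path) -> None:
    cols = [c for c in table.data.columns if c in THICKNESS_META_COLUMNS]
    extra = [c for c in table.data.columns
             if c not in THICKNESS_META_COLUMNS and c not in table.roi_columns]
    table.data[cols + extra + table.roi_columns].to_csv(path, sep="\t", index=False)


def read_thickness(path, parcellation: Parcellation | None = None) -> RegionalThicknessTable:
    """Read and validate a long-format thickness TSV.

    With a parcellation, ROI columns are matched by name and every
    expected ``roi_<id>`` column must be present.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in THICKNESS_META_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing columns {missing}")
    roi_cols = [c for c in df.columns if c.startswith("roi_")]
    if parcellation is not None:
        expected = [f"roi_{i}" for i in parcellation.roi_ids]
        absent = [c for c in expected if c not in df.columns]
        if absent:
            raise InvalidInputError(f"{path}: missing ROI columns {absent}")
        roi_cols = expected
    bad = df[roi_cols].apply(lambda c: pd.to_numeric(c, errors="coerce")).isna()
    if bad.to_numpy().any():
        rows = np.flatnonzero(bad.any(axis=1))[:5] + 2  # 1-based + header
        raise InvalidInputError(f"{path}: non-numeric thickness near lines {rows.tolist()}")
    return RegionalThicknessTable(data=df, roi_columns=roi_cols)


# ---------------------------------------------------------------------------
# parcellation / connectome / expression
# ---------------------------------------------------------------------------

def write_parcellation(parcellation: Parcellation, path) -> None:
    parcellation.to_frame().to_csv(path, sep="\t", index=False)


def read_parcellation(path) -> Parcellation:
    return Parcellation.from_frame(pd.read_csv(path, sep="\t"))


def write_connectome(template: ConnectivityTemplate, path) -> None:
    R = template.n_rois
    cols = [f"roi_{i}" for i in range(R)]
    pd.DataFrame(template.weights, columns=cols).to_csv(path, sep="\t", index=False)


def read_connectome(path, parcellation: Parcellation, modality: str) -> ConnectivityTemplate:
    df = pd.read_csv(path, sep="\t")
    expected = [f"roi_{i}" for i in parcellation.roi_ids]
    if list(df.columns) != expected:
        raise InvalidInputError(f"{path}: connectome columns do not match parcellation")
    return ConnectivityTemplate(
        weights=df.to_numpy(float), modality=modality, distances=parcellation.distances
    )


def write_expression(expr: ExpressionMatrix, path) -> None:
    df = expr.to_frame()
    df.insert(0, "roi_id", np.arange(df.shape[0]))
    df.to_csv(path, sep="\t", index=False)
    Path(str(path) + ".sources.json").write_text(
        json.dumps(dict(zip(expr.gene_symbols, expr.gene_source)), indent=0)
    )


def read_expression(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t")
    genes = [c for c in df.columns if c != "roi_id"]
    sources_path = Path(str(path) + ".sources.json")
    if sources_path.exists():
        smap = json.loads(sources_path.read_text())
        sources = [smap.get(g, "other") for g in genes]
    else:
        sources = ["other"] * len(genes)
    return ExpressionMatrix(expr=df[genes].to_numpy(float), gene_symbols=genes,
                            gene_source=sources)


# ---------------------------------------------------------------------------
# model / betamaps / truth
# ---------------------------------------------------------------------------

def model_to_json(model: SubtypeModel) -> dict:
    return {
        "k": model.k,
        "W": model.W.tolist(),
        "H": model.H.tolist(),
        "rss": model.rss,
        "subject_ids": [str(s) for s in model.subject_ids],
        "subject_assignment": model.subject_assignment.tolist(),
        "subject_probability": model.subject_probability.tolist(),
        "region_assignment": model.region_assignment.tolist(),
        "consensus": model.consensus.tolist(),
        "inversion_offsets": (
            None if model.inversion_offsets is None else model.inversion_offsets.tolist()
        ),
        "unassignable": (
            None if model.unassignable is None else model.unassignable.astype(int).tolist()
        ),
    }


def write_model(model: SubtypeModel, path) -> None:
    Path(path).write_text(json.dumps(model_to_json(model)))


def read_model(path) -> SubtypeModel:
    d = json.loads(Path(path).read_text())
    return SubtypeModel(
        k=d["k"],
        W=np.asarray(d["W"], float),
        H=np.asarray(d["H"], float),
        rss=float(d["rss"]),
        subject_ids=np.asarray(d["subject_ids"]),
        subject_assignment=np.asarray(d["subject_assignment"], int),
        subject_probability=np.asarray(d["subject_probability"], float),
        region_assignment=np.asarray(d["region_assignment"], int),
        consensus=np.asarray(d["consensus"], float),
        inversion_offsets=(
            None if d["inversion_offsets"] is None
            else np.asarray(d["inversion_offsets"], float)
        ),
        unassignable=(
            None if d["unassignable"] is None
            else np.asarray(d["unassignable"], int).astype(bool)
        ),
    )


def write_betamaps(maps: list[BetaMap], path) -> None:
    rows = []
    for m in maps:
        for r in range(len(m.beta)):
            rows.append((r, m.subtype_label, m.beta[r], m.se[r], m.p[r]))
    pd.DataFrame(rows, columns=["roi_id", "subtype", "beta", "se", "p"]).to_csv(
        path, sep="\t", index=False
    )


def read_betamaps(path) -> list[BetaMap]:
    df = pd.read_csv(path, sep="\t")
    maps = []
    for label, grp in df.groupby("subtype"):
        grp = grp.sort_values("roi_id")
        maps.append(BetaMap(subtype_label=int(label),
                            beta=grp["beta"].to_numpy(float),
                            se=grp["se"].to_numpy(float),
                            p=grp["p"].to_numpy(float)))
    return maps


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PipelineConfig:
    """Paths and knobs for the end-to-end pipeline."""

    thickness: str = ""
    parcellation: str = ""
    templates: dict[str, str] = dataclasses.field(default_factory=dict)
    expression: str = ""
    gmt: str = ""
    out_dir: str = "cortsub_run"
    k_range: list[int] = dataclasses.field(default_factory=lambda: [2, 3, 4, 5, 6])
    n_restarts: int = 50
    n_perm: int = 1000
    n_surr: int = 1000
    alpha_threshold: float = 0.05
    seed: int = 0
    invert_global_max: bool = False
    cdm_normalized: bool = True
    gene_two_sided: bool = True
    followup_use_inverted: bool = True
    run_genes: bool = True
    run_cdm: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if not 0 < cfg.alpha_threshold < 1:
            raise InvalidArgumentError("alpha_threshold must be in (0, 1)")
        for name in ("n_restarts", "n_perm", "n_surr"):
            if getattr(cfg, name) < 1:
                raise InvalidArgumentError(f"{name} must be positive")
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
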