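"""Docking-score triage: screening, refinement, co-crystal validation,
target classification and ligand-target network export.

The funnel mirrors an inverse virtual-screening workflow in which one ligand
is docked against a receptor panel:

1. ``screen_filter``  — keep complexes scoring at or below -8.0 kcal/mol;
2. ``refine_filter``  — keep complexes scoring at or below -9.0 kcal/mol;
3. ``validate``       — keep complexes scoring strictly better (more
   negative) than the redocked co-crystallized ligand of the same receptor;
4. ``classify_targets`` — label survivors strong (score <= -10.0) or weak
   (-10.0 < score <= -9.0).

Score thresholds are inclusive: a complex scoring exactly -8.0 kcal/mol
passes the -8.0 screen (receptor panels conventionally report scores to one
decimal and count the boundary as passing).  The validation comparison is
strict: a tie with the co-crystal ligand fails.

Tables are plain pandas DataFrames with the columns in :data:`COLUMNS`.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COLUMNS = [
    "ligand_id",
    "target_id",
    "category",
    "structure_id",
    "score_kcal_mol",
    "cocrystal_score_kcal_mol",
    "stage",
    "class_label",
]

STAGES = ["input", "screened", "refined", "validated"]

SCREEN_THRESHOLD = -8.0
REFINE_THRESHOLD = -9.0
STRONG_THRESHOLD = -10.0

__all__ = [
    "COLUMNS",
    "STAGES",
    "SCREEN_THRESHOLD",
    "REFINE_THRESHOLD",
    "STRONG_THRESHOLD",
    "new_table",
    "validate_table",
    "dedupe",
    "screen_filter",
    "refine_filter",
    "validate",
    "classify_targets",
    "build_network",
    "read_score_csv",
    "write_score_csv",
    "write_network",
]


def new_table(rows: list[dict]) -> pd.DataFrame:
    """Build a score table, filling stage/class defaults."""
    df = pd.DataFrame(rows)
    for col in COLUMNS:
        if col not in df.columns:
            df[col] = np.nan if col.endswith("kcal_mol") else None
    df["stage"] = df["stage"].fillna("input") if len(df) else df["stage"]
    df["class_label"] = df["class_label"].fillna("none") if len(df) else df["class_label"]
    df = df[COLUMNS]
    validate_table(df)
    return df


def validate_table(df: pd.DataFrame) -> None:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"score table missing columns {missing}")
    if len(df) and not np.all(np.isfinite(df["score_kcal_mol"].to_numpy(dtype=float))):
        raise ValueError("non-finite docking scores in table")


def dedupe(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate (ligand, target) rows keeping the best (most
    negative) score; collisions are logged."""
    validate_table(df)
    if df.duplicated(["ligand_id", "target_id"]).any():
        n = int(df.duplicated(["ligand_id", "target_id"]).sum())
        logger.warning("collapsing %d duplicate (ligand,target) rows", n)
        df = (
            df.sort_values("score_kcal_mol", kind="stable")
            .drop_duplicates(["ligand_id", "target_id"], keep="first")
            .sort_index()
        )
    return df.reset_index(drop=True)


def _stage_at_least(df: pd.DataFrame, stage: str) -> None:
    order = {s: i for i, s in enumerate(STAGES)}
    need = order[stage]
    bad = df["stage"].map(lambda s: order.get(s, -1) < need)
    if bad.any():
        raise ValueError(
            f"pipeline order violation: {int(bad.sum())} rows have not reached "
            f"stage {stage!r}"
        )


def screen_filter(df: pd.DataFrame, threshold: float = SCREEN_THRESHOLD) -> pd.DataFrame:
    """Initial screen: keep rows scoring at or below the threshold and stamp
    them stage='screened'.  Idempotent and order-preserving."""
    validate_table(df)
    out = df[df["score_kcal_mol"] <= threshold].copy()
    out["stage"] = "screened"
    return out.reset_index(drop=True)


def refine_filter(df: pd.DataFrame, threshold: float = REFINE_THRESHOLD) -> pd.DataFrame:
    """Refinement: keep screened rows at or below the threshold (stage='refined')."""
    validate_table(df)
    _stage_at_least(df, "screened")
    out = df[df["score_kcal_mol"] <= threshold].copy()
    out["stage"] = "refined"
    return out.reset_index(drop=True)


def validate(df: pd.DataFrame) -> pd.DataFrame:
    """Co-crystal validation: retain rows whose score is strictly more
    negative than the redocked co-crystallized ligand's score."""
    validate_table(df)
    cc = df["cocrystal_score_kcal_mol"]
    if len(df) and cc.isna().any():
        bad = df[cc.isna()].iloc[0]
        raise ValueError(
            "missing co-crystal score for "
            f"({bad['ligand_id']}, {bad['target_id']})"
        )
    out = df[df["score_kcal_mol"] < cc].copy()
    out["stage"] = "validated"
    return out.reset_index(drop=True)


def classify_targets(df: pd.DataFrame) -> pd.DataFrame:
    """Label validated rows: strong if score <= -10.0 kcal/mol, weak if
    -10.0 < score <= -9.0, none otherwise."""
    validate_table(df)
    _stage_at_least(df, "validated")
    out = df.copy()
    s = out["score_kcal_mol"]
    out["class_label"] = np.where(
        s <= STRONG_THRESHOLD, "strong", np.where(s <= REFINE_THRESHOLD, "weak", "none")
    )
    return out.reset_index(drop=True)


def build_network(df: pd.DataFrame, stage: str = "validated") -> nx.Graph:
    """Bipartite ligand-target network for rows at the given stage.

    Edge weight is |score| in kcal/mol; nodes are added in lexicographic
    order for deterministic serialization.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    validate_table(df)
    rows = df[df["stage"] == stage]
    g = nx.Graph()
    for lig in sorted(rows["ligand_id"].astype(str).unique()):
        g.add_node(lig, bipartite="ligand")
    for tgt in sorted(rows["target_id"].astype(str).unique()):
        g.add_node(tgt, bipartite="target")
    for _, row in rows.sort_values(["ligand_id", "target_id"], kind="stable").iterrows():
        g.add_edge(
            str(row["ligand_id"]),
            str(row["target_id"]),
            weight=float(abs(row["score_kcal_mol"])),
            category=str(row["category"]),
        )
    return g


def read_score_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    rename = {"score": "score_kcal_mol", "cocrystal_score": "cocrystal_score_kcal_mol"}
    df = df.rename(columns=rename)
    return new_table(df.to_dict("records"))


def write_score_csv(df: pd.DataFrame, path) -> None:
    validate_table(df)
    df.to_csv(path, index=False)


def write_network(g: nx.Graph, edge_tsv_path=None, graphml_path=None) -> None:
    if edge_tsv_path is not None:
        rows = [
            {"ligand": u, "target": v, "weight": d["weight"], "category": d["category"]}
            for u, v, d in sorted(g.edges(data=True))
        ]
        pd.DataFrame(rows, columns=["ligand", "target", "weight", "category"]).to_csv(
            edge_tsv_path, sep="\t", index=False
        )
    if graphml_path is not None:
        nx.write_graphml(g, graphml_path)
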