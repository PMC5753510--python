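"""Readers and writers for the plain-text formats the pipeline exchanges.

Studies, mention tables, prediction matrices, edge lists and result tables
travel as TSV; gene-set collections as GMT (name, description, members);
analysis bundles as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .consensus import PredictionMatrix
from .enrichment import EnrichmentResult, GeneSetCollection
from .meta import EffectEstimate, GroupSummary, PooledResult, StudyRecord
from .mining import CocitationResult, results_frame
from .network import EdgeRecord, HubResult

__all__ = [
    "read_studies_tsv", "write_studies_tsv",
    "read_mentions_tsv", "write_mentions_tsv",
    "read_predictions_tsv", "write_predictions_tsv",
    "read_gmt", "write_gmt",
    "read_edges_tsv", "write_edges_tsv",
    "write_forest_tsv", "write_cocitation_tsv", "write_enrichment_tsv",
    "write_hub_tsv", "write_json",
]


# -- studies ---------------------------------------------------------------

def write_studies_tsv(studies: Sequence[StudyRecord], path: str | Path) -> None:
    """Long format: one row per (study, group)."""
    rows = []
    for s in studies:
        rows.append((s.study_id, "case", s.case.n, s.case.mean, s.case.sd, s.stratum))
        rows.append((s.study_id, "control", s.control.n, s.control.mean,
                     s.control.sd, s.stratum))
    frame = pd.DataFrame(rows, columns=["study_id", "group", "n", "mean", "sd", "stratum"])
    # repr emits the shortest digit string that round-trips the float exactly
    frame.to_csv(path, sep="\t", index=False,
                 float_format=lambda x: repr(float(x)))


def read_studies_tsv(path: str | Path) -> list[StudyRecord]:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    studies = []
    for study_id, grp in frame.groupby("study_id", sort=False):
        by_group = {row["group"]: row for _, row in grp.iterrows()}
        if set(by_group) != {"case", "control"}:
            raise ValueError(f"study {study_id!r} needs exactly one case and one control row")
        case, control = by_group["case"], by_group["control"]
        studies.append(
            StudyRecord(
                study_id=str(study_id),
                case=GroupSummary(n=int(case["n"]), mean=float(case["mean"]),
                                  sd=float(case["sd"])),
                control=GroupSummary(n=int(control["n"]), mean=float(control["mean"]),
                                     sd=float(control["sd"])),
                stratum=str(case["stratum"]),
            )
        )
    return studies


# -- mention tables --------------------------------------------------------

def write_mentions_tsv(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    out["disease_flag"] = out["disease_flag"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_mentions_tsv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", keep_default_na=False,
                        dtype={"doc_id": str, "genes": str})
    frame["disease_flag"] = frame["disease_flag"].astype(bool)
    return frame


# -- prediction matrices ---------------------------------------------------

def write_predictions_tsv(matrix: PredictionMatrix, path: str | Path) -> None:
    frame = matrix.to_frame()
    frame.index.name = "gene"
    frame.to_csv(path, sep="\t")


def read_predictions_tsv(path: str | Path) -> PredictionMatrix:
    frame = pd.read_csv(path, sep="\t", index_col="gene")
    return PredictionMatrix.from_frame(frame)


# -- gene sets (GMT) -------------------------------------------------------

def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_gmt(path: str | Path, category: str = "pathway",
             universe: Iterable[str] | None = None) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{line_no}: GMT line needs name, "
                                 "description and at least one member")
            sets[fields[0]] = fields[2:]
    return GeneSetCollection.from_sets(sets, categories=category, universe=universe)


# -- edges -----------------------------------------------------------------

def write_edges_tsv(edges: Sequence[EdgeRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        [(e.source, e.target, e.interaction_type, e.polarity) for e in edges],
        columns=["source", "target", "type", "polarity"],
    )
    frame.to_csv(path, sep="\t", index=False)


def read_edges_tsv(path: str | Path) -> list[EdgeRecord]:
    edges = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["source", "target", "type", "polarity"]
        if header != expected:
            raise ValueError(f"{path}:1: expected header {expected}, got {header}")
        for line_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{line_no}: expected 4 fields, got {len(fields)}")
            try:
                edges.append(EdgeRecord(source=fields[0], target=fields[1],
                                        interaction_type=fields[2], polarity=fields[3]))
            except ValueError as exc:
                raise ValueError(f"{path}:{line_no}: {exc}") from exc
    return edges


# -- result tables ---------------------------------------------------------

def write_forest_tsv(rows: Sequence[dict], path: str | Path) -> None:
    pd.DataFrame(rows, columns=["study_id", "g", "ci_low", "ci_high",
                                "weight_percent"]).to_csv(path, sep="\t", index=False)


def write_cocitation_tsv(results: Sequence[CocitationResult], path: str | Path) -> None:
    results_frame(results).to_csv(path, sep="\t", index=False)


def write_enrichment_tsv(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            (r.set_name, r.category, r.overlap_count, r.set_size, r.p,
             ";".join(r.overlap_genes), int(r.significant))
            for r in results
        ],
        columns=["term", "category", "count", "set_size", "p_value", "genes",
                 "significant"],
    )
    frame.to_csv(path, sep="\t", index=False)


def write_hub_tsv(hubs: Sequence[HubResult], path: str | Path) -> None:
    pd.DataFrame(
        [(h.node, h.degree, h.z, h.p, int(h.degenerate)) for h in hubs],
        columns=["node", "degree", "z", "p", "degenerate"],
    ).to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
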