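"""Readers and writers for the plain-text formats used across the pipeline.

Expression matrices, edge lists, arc lists, id lists and GMT annotation
collections are all tab-separated text.  Interaction confidences accept both
the 0-999 integer dialect of combined scores (divided by 1000) and plain
reals in [0, 1]; the dialect is auto-detected per file.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .clustering import SAMPLES, validate_expression
from .network import RegArc, ScoredEdge, dedupe_edges


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return validate_expression(df)


def write_expression(matrix: pd.DataFrame, path) -> None:
    out = validate_expression(matrix).copy()
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t")


def _normalise_scores(scores: pd.Series) -> pd.Series:
    """Auto-detect the score dialect: 0-999 integer scores are /1000."""
    s = pd.to_numeric(scores)
    if s.max() > 1.0:
        return s / 1000.0
    return s


def read_edges(path) -> list[ScoredEdge]:
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    conf = _normalise_scores(df.iloc[:, 2])
    edges = [ScoredEdge(str(a), str(b), float(c))
             for a, b, c in zip(df.iloc[:, 0], df.iloc[:, 1], conf)]
    return dedupe_edges(edges)


def write_edges(edges: list[ScoredEdge], path) -> None:
    pd.DataFrame(
        [(e.a, e.b, e.confidence) for e in edges],
        columns=["protein_a", "protein_b", "confidence"],
    ).to_csv(path, sep="\t", index=False)


def read_arcs(path) -> list[RegArc]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [RegArc(str(tf), str(tg))
            for tf, tg in zip(df.iloc[:, 0], df.iloc[:, 1])]


def write_arcs(arcs: list[RegArc], path) -> None:
    pd.DataFrame([(a.tf, a.target) for a in arcs],
                 columns=["tf", "target"]).to_csv(path, sep="\t", index=False)


def read_id_list(path) -> list[str]:
    text = Path(path).read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


def write_id_list(ids, path) -> None:
    Path(path).write_text("".join(f"{i}\n" for i in sorted(ids)))


def read_gmt(path) -> dict[str, set[str]]:
    """GMT: term <tab> description <tab> member1 <tab> member2 ..."""
    annotations: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        annotations[fields[0]] = set(fields[2:])
    return annotations


def write_gmt(annotations: dict[str, set[str]], path,
              descriptions: dict[str, str] | None = None) -> None:
    lines = []
    for term in sorted(annotations):
        desc = (descriptions or {}).get(term, "na")
        members = "\t".join(sorted(annotations[term]))
        lines.append(f"{term}\t{desc}\t{members}\n")
    Path(path).write_text("".join(lines))


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
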