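"""TREC-style retrieval evaluation: nDCG@K, MAP@K, precision@N.

Conventions follow the common trec_eval behaviour: linear nDCG gain
(``rel_r / log2(r + 1)``), AP truncated at rank K but normalized by the total
number of relevant documents R, and binarization at grade >= 1 for P@N and
MAP (graded judgments 0/1/2).  Topics with no relevant documents are excluded
from metric means rather than scored 0.

Qrels lines are whitespace-separated ``topic 0 docid grade``; run lines are
``topic Q0 docid rank score tag``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence


@dataclass
class Qrels:
    """Graded relevance judgments: (topic, doc) -> integer grade >= 0."""

    grades: dict[tuple[str, str], int] = field(default_factory=dict)

    def add(self, topic: str, doc_id: str, grade: int) -> None:
        if grade < 0:
            raise ValueError("relevance grades must be non-negative")
        self.grades[(topic, doc_id)] = grade

    def topics(self) -> set[str]:
        return {t for t, _ in self.grades}

    def for_topic(self, topic: str) -> dict[str, int]:
        return {d: g for (t, d), g in self.grades.items() if t == topic}


@dataclass
class Run:
    """Per-topic rankings: topic -> ordered (doc_id, score) list."""

    rankings: dict[str, list[tuple[str, float]]] = field(default_factory=dict)

    def topics(self) -> set[str]:
        return set(self.rankings)


@dataclass
class MetricReport:
    per_topic: dict[str, dict[str, float]]
    means: dict[str, float]

    def to_table(self) -> str:
        metrics = sorted(self.means)
        lines = ["topic\t" + "\t".join(metrics)]
        for topic in sorted(self.per_topic):
            row = self.per_topic[topic]
            lines.append(
                topic + "\t" + "\t".join(f"{row[m]:.4f}" for m in metrics)
            )
        lines.append("mean\t" + "\t".join(f"{self.means[m]:.4f}" for m in metrics))
        return "\n".join(lines)


def precision_at(ranking: Sequence[str], grades: Mapping[str, int], n: int) -> float:
    """Fraction of the top-n ranked docs that are relevant (grade >= 1).

    Rankings shorter than n count the missing slots as non-relevant.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    hits = sum(1 for d in ranking[:n] if grades.get(d, 0) >= 1)
    return hits / n


def average_precision_at(
    ranking: Sequence[str], grades: Mapping[str, int], k: int
) -> float | None:
    """AP truncated at rank k, normalized by the total relevant count R.

    Returns None when the topic has no relevant documents (undefined; the
    topic is then excluded from the mean).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    total_relevant = sum(1 for g in grades.values() if g >= 1)
    if total_relevant == 0:
        return None
    score = 0.0
    hits = 0
    for rank, doc_id in enumerate(ranking[:k], 1):
        if grades.get(doc_id, 0) >= 1:
            hits += 1
            score += hits / rank
    return score / total_relevant


def dcg(gains: Sequence[float]) -> float:
    return sum(g / math.log2(r + 1) for r, g in enumerate(gains, 1))


def ndcg_at(ranking: Sequence[str], grades: Mapping[str, int], k: int) -> float | None:
    """nDCG@k with linear gain; None when the ideal DCG is 0 (no relevant)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ideal = dcg(sorted(grades.values(), reverse=True)[:k])
    if ideal == 0:
        return None
    actual = dcg([grades.get(d, 0) for d in ranking[:k]])
    return actual / ideal


def evaluate(
    run: Run,
    qrels: Qrels,
    ndcg_cutoff: int = 10,
    map_cutoff: int = 10,
    precision_cutoffs: Sequence[int] = (5, 10),
) -> MetricReport:
    """Per-topic metrics and means over topics with any relevant document."""
    shared = sorted(run.topics() & qrels.topics())
    if not shared:
        raise ValueError("run and qrels share no topics")
    per_topic: dict[str, dict[str, float]] = {}
    for topic in shared:
        grades = qrels.for_topic(topic)
        if not any(g >= 1 for g in grades.values()):
            continue  # excluded from means: metrics undefined/degenerate
        ranking = [d for d, _ in run.rankings[topic]]
        row = {
            f"ndcg@{ndcg_cutoff}": ndcg_at(ranking, grades, ndcg_cutoff),
            f"map@{map_cutoff}": average_precision_at(ranking, grades, map_cutoff),
        }
        for n in precision_cutoffs:
            row[f"p@{n}"] = precision_at(ranking, grades, n)
        per_topic[topic] = row  # type: ignore[assignment]
    if not per_topic:
        raise ValueError("no topic has relevant documents; metrics undefined")
    metric_names = next(iter(per_topic.values())).keys()
    means = {
        m: sum(row[m] for row in per_topic.values()) / len(per_topic)
        for m in metric_names
    }
    return MetricReport(per_topic=per_topic, means=means)


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def read_qrels(path: str | Path) -> Qrels:
    qrels = Qrels()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) != 4:
            raise ValueError(f"malformed qrels line {lineno}: {line!r}")
        topic, _, doc_id, grade = parts
        qrels.add(topic, doc_id, int(grade))
    return qrels


def write_qrels(qrels: Qrels, path: str | Path) -> None:
    with Path(path).open("w") as handle:
        for (topic, doc_id), grade in sorted(qrels.grades.items()):
            handle.write(f"{topic} 0 {doc_id} {grade}\n")


def read_run(path: str | Path) -> Run:
    rows: dict[str, list[tuple[int, str, float]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) != 6:
            raise ValueError(f"malformed run line {lineno}: {line!r}")
        topic, _, doc_id, rank, score, _tag = parts
        rows.setdefault(topic, []).append((int(rank), doc_id, float(score)))
    run = Run()
    for topic, entries in rows.items():
        entries.sort()
        docs = [d for _, d, _ in entries]
        if len(set(docs)) != len(docs):
            raise ValueError(f"duplicate doc_id in run for topic {topic}")
        run.rankings[topic] = [(d, s) for _, d, s in entries]
    return run
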