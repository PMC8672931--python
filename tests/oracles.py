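"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive every quantity from first principles with naive
data structures (string padding for containment, explicit all-pairs loops,
permutation search for ideal rankings) so they share no code path with the
package modules they check.
"""

from __future__ import annotations

import itertools
import math


# --- C-value ---------------------------------------------------------------

def oracle_cvalue(candidates):
    """(surface -> cvalue) by explicit enumeration of containing sets."""
    out = {}
    for a in candidates:
        padded_a = f" {a.surface} "
        containing = [
            b for b in candidates
            if b.length > a.length and padded_a in f" {b.surface} "
        ]
        if containing:
            raw = a.freq - sum(b.freq for b in containing) / len(containing)
        else:
            raw = a.freq
        out[a.surface] = max(0.0, math.log2(a.length) * raw)
    return out


def oracle_ngram_counts(chunks, min_len, max_len):
    """n-gram frequencies over explicit word-list chunks."""
    counts = {}
    for chunk in chunks:
        for length in range(min_len, max_len + 1):
            for start in range(len(chunk) - length + 1):
                key = " ".join(chunk[start : start + length])
                counts[key] = counts.get(key, 0) + 1
    return counts


# --- graph edge weights ----------------------------------------------------

def oracle_direct_weights(mentions, years, sections_weight):
    """(citing, cited) -> weight by direct formula over the mention table.

    *mentions*: iterable of (citing, cited, section); *years*: doc -> year or
    None; *sections_weight*: section -> sw (with 'other' fallback).
    """
    pairs = {}
    for citing, cited, section in mentions:
        pairs.setdefault((citing, cited), []).append(section)
    out = {}
    for (citing, cited), secs in pairs.items():
        n = len(secs)
        sw = max(sections_weight.get(s, sections_weight["other"]) for s in secs)
        ya, yb = years.get(citing), years.get(cited)
        denom = 1 if ya is None or yb is None else max(1, ya - yb)
        out[(citing, cited)] = n * sw / denom
    return out


def oracle_indirect_weights(doc_ids, mentions, years, sections_weight):
    """Unordered-pair -> co-citation weight by explicit set intersection."""
    direct = oracle_direct_weights(mentions, years, sections_weight)
    cited_sets = {d: set() for d in doc_ids}
    for citing, cited, _ in mentions:
        if citing in cited_sets:
            cited_sets[citing].add(cited)
    out = {}
    for a, b in itertools.combinations(sorted(doc_ids), 2):
        common = cited_sets[a] & cited_sets[b]
        if not common:
            continue
        total = sum(
            direct.get((a, c), 0.0) + direct.get((b, c), 0.0) for c in common
        )
        out[(a, b)] = total / (2 * len(common))
    return out


def oracle_term_edges(doc_ids, top_profiles):
    """Unordered-pair -> {term: weight}; *top_profiles*: doc -> {term: cv}."""
    out = {}
    for a, b in itertools.combinations(sorted(doc_ids), 2):
        shared = set(top_profiles[a]) & set(top_profiles[b])
        if shared:
            out[(a, b)] = {
                t: (top_profiles[a][t] + top_profiles[b][t]) / 2 for t in shared
            }
    return out


# --- IR metrics ------------------------------------------------------------

def oracle_precision(ranking, grades, n):
    return sum(1 for d in ranking[:n] if grades.get(d, 0) > 0) / n


def oracle_ap(ranking, grades, k):
    relevant = {d for d, g in grades.items() if g > 0}
    if not relevant:
        return None
    total, hits = 0.0, 0
    for rank, doc in enumerate(ranking[:k], 1):
        if doc in relevant:
            hits += 1
            total += hits / rank
    return total / len(relevant)


def oracle_ndcg_permutation(ranking, grades, k):
    """nDCG with the ideal DCG found by exhaustive permutation search."""
    def dcg_of(docs):
        return sum(
            grades.get(d, 0) / math.log2(r + 1) for r, d in enumerate(docs[:k], 1)
        )

    universe = sorted(grades)
    best = 0.0
    for perm in itertools.permutations(universe):
        best = max(best, dcg_of(list(perm)))
    if best == 0:
        return None
    return dcg_of(list(ranking)) / best
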