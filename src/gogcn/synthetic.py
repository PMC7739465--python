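"""Synthetic desk-scale benchmark: a GO-like DAG, TPR-closed multi-label
annotations, and sequences carrying implanted function motifs.

Each leaf term owns a distinct short motif. A protein samples its leaf
annotations independently (Bernoulli per leaf, resampled so every protein
keeps at least one), inherits all ancestors under the True Path Rule, and
its sequence is uniform background with each owned leaf's motif implanted
at a random non-overlapping position — so the sequence→function mapping
is exactly learnable and a trained model has a clean ceiling. A
``motif_noise`` option drops implants with stated probability for harder
variants. The generator emulates annotation-frequency imbalance (deep
terms rare, shallow terms common) but not real GO topology statistics or
homology between proteins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotations import AnnotationTable
from .ontology import OntologyGraph
from .sequences import ALPHABET


@dataclass
class SynthConfig:
    """Generator settings; defaults give the desk-scale study conditions."""

    n_terms: int = 40
    n_levels: int = 3
    max_parents: int = 2
    n_proteins: int = 300
    seq_length: int = 300
    motif_length: int = 5
    leaf_annotation_prob: float = 0.3
    motif_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_levels < 2 and self.n_terms > 1:
            raise ValueError("need at least 2 levels for a non-trivial DAG")
        if self.motif_length >= self.seq_length:
            raise ValueError("motif_length must be smaller than seq_length")
        if not 0.0 < self.leaf_annotation_prob < 1.0:
            raise ValueError("leaf_annotation_prob must be in (0, 1)")


def _term_id(i: int) -> str:
    return f"GO:{i + 1:07d}"


def generate_dag(config: SynthConfig) -> OntologyGraph:
    """Rooted layered DAG: one root; each deeper node draws 1..max_parents
    parents uniformly from the previous level (acyclic by construction)."""
    rng = np.random.default_rng(config.seed)
    terms = [_term_id(i) for i in range(config.n_terms)]
    if config.n_terms == 1:
        return OntologyGraph(terms=set(terms), edges=set(),
                             namespace={terms[0]: "BP"})
    # spread the non-root terms over levels 2..n_levels, deeper levels
    # larger; drop unfillable levels so none is ever empty
    n_rest = config.n_terms - 1
    n_sublevels = min(config.n_levels - 1, n_rest)
    weights = np.arange(1, n_sublevels + 1)
    sizes = np.maximum(1, (n_rest * weights / weights.sum()).astype(int))
    while sizes.sum() > n_rest:
        sizes[np.argmax(sizes)] -= 1
    while sizes.sum() < n_rest:
        sizes[-1] += 1
    levels = [[terms[0]]]
    cursor = 1
    for size in sizes:
        levels.append(terms[cursor:cursor + size])
        cursor += size
    edges = set()
    for prev, level in zip(levels, levels[1:]):
        for t in level:
            k = int(rng.integers(1, min(config.max_parents, len(prev)) + 1))
            parents = rng.choice(len(prev), size=k, replace=False)
            for p in parents:
                edges.add((t, prev[p], "is_a"))
    return OntologyGraph(terms=set(terms), edges=edges,
                         namespace={t: "BP" for t in terms})


def _sample_motifs(leaves, config: SynthConfig, rng) -> dict:
    alphabet = np.array(list(ALPHABET))
    motifs: dict = {}
    used: set = set()
    for leaf in leaves:
        while True:
            m = "".join(rng.choice(alphabet, size=config.motif_length))
            if m not in used:
                used.add(m)
                motifs[leaf] = m
                break
    return motifs


def _place_motifs(seq: np.ndarray, motifs, config: SynthConfig, rng) -> None:
    """Implant motifs at random non-overlapping positions, in place."""
    L, w = config.seq_length, config.motif_length
    if len(motifs) * w > L:
        raise ValueError(
            f"cannot place {len(motifs)} motifs of length {w} in a sequence "
            f"of length {L} without overlap; increase seq_length"
        )
    taken: list = []
    for motif in motifs:
        for _ in range(1000):
            start = int(rng.integers(0, L - w + 1))
            if all(start + w <= s or start >= s + w for s, _ in taken):
                taken.append((start, motif))
                break
        else:
            raise ValueError(
                "could not place motifs without overlap; increase seq_length"
            )
    for start, motif in taken:
        seq[start:start + w] = list(motif)


def generate_proteins(graph: OntologyGraph, config: SynthConfig):
    """Sequences plus TPR-closed annotations.

    Returns ``(records, table, motifs)``: FASTA-style ``(id, seq)`` pairs,
    the closed :class:`AnnotationTable`, and the leaf→motif map.
    """
    rng = np.random.default_rng(config.seed + 1)
    leaves = sorted(t for t in graph.terms if not graph.children(t))
    motifs = _sample_motifs(leaves, config, rng)
    alphabet = np.array(list(ALPHABET))
    records = []
    table: dict = {}
    for i in range(config.n_proteins):
        pid = f"P{i + 1:05d}"
        while True:
            owned = [
                leaf for leaf in leaves
                if rng.random() < config.leaf_annotation_prob
            ]
            if owned:
                break
        seq = rng.choice(alphabet, size=config.seq_length)
        implanted = [
            motifs[leaf] for leaf in owned
            if config.motif_noise == 0.0 or rng.random() >= config.motif_noise
        ]
        _place_motifs(seq, implanted, config, rng)
        records.append((pid, "".join(seq)))
        closed = set(owned)
        for leaf in owned:
            closed.update(graph.ancestors(leaf))
        table[pid] = closed
    return records, AnnotationTable(proteins=table, propagated=True), motifs


# -- plain-text writers (OBO / FASTA / TSV) ------------------------------

def write_obo(graph: OntologyGraph, path) -> None:
    ns_names = {"BP": "biological_process", "MF": "molecular_function",
                "CC": "cellular_component"}
    parents: dict = {t: [] for t in graph.terms}
    for child, parent, rel in sorted(graph.edges):
        parents[child].append((parent, rel))
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic\n")
        for t in sorted(graph.terms):
            fh.write(f"\n[Term]\nid: {t}\nname: synthetic term {t}\n")
            ns = graph.namespace.get(t)
            if ns:
                fh.write(f"namespace: {ns_names.get(ns, ns)}\n")
            for parent, rel in parents[t]:
                if rel == "is_a":
                    fh.write(f"is_a: {parent} ! parent\n")
                else:
                    fh.write(f"relationship: {rel} {parent} ! parent\n")


def write_fasta(records, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for pid, seq in records:
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_annotations_tsv(table: AnnotationTable, path) -> None:
    with open(path, "w") as fh:
        for protein in sorted(table.proteins):
            for term in sorted(table[protein]):
                fh.write(f"{protein}\t{term}\n")
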