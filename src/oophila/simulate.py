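"""Synthetic clone-library surveys with known ground truth.

The generator emulates a multi-host, multi-site egg-capsule survey: each
capsule yields ``n`` cloned 18S rDNA sequences, each clone independently a
non-target contaminant with per-capsule incidence ``q``; target clones are
copies of one of four divergent subclade reference sequences (chosen by a
per-capsule mixture) with independent per-site substitution noise.

Reference panels are built to hit a requested pairwise-divergence matrix:
the matrix is fitted to an unrooted tree (non-negative least squares on the
path/edge incidence system), each edge is given a disjoint set of mutated
columns, so realized leaf-to-leaf divergences are exactly the rounded path
sums.  No indels are simulated, so synthetic alignments are gap-free and
uncorrected p-distances on them are exact.

Determinism: one integer seed drives the survey; per-capsule generators are
derived by hashing (capsule_id, seed), so outputs do not depend on the order
in which capsules are generated.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .distances import p_distance_pair
from .io import AlignedSeqSet, SampleManifest, SampleRow, write_aligned_fasta, write_manifest

__all__ = [
    "NON_TARGET",
    "SubcladePanel",
    "Clone",
    "CapsuleLibrary",
    "SyntheticSurvey",
    "DesignRow",
    "InfeasibleDivergenceError",
    "default_divergence_matrix",
    "simulate_references",
    "simulate_capsule_library",
    "simulate_survey",
    "survey_design",
    "write_survey",
]

#: Truth label for contaminant (non-symbiont) clones.
NON_TARGET = "NON_TARGET"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]

#: Divergence floor (proportion) between contaminant clones and every
#: subclade reference.  The study system does not pin this down; 18S rDNA of
#: unrelated green algae differs from the symbiont clade by well over this.
NON_TARGET_MIN_DIVERGENCE = 0.10


class InfeasibleDivergenceError(ValueError):
    """Requested pairwise divergences cannot be realized on any tree."""


def default_divergence_matrix() -> np.ndarray:
    """Default 4-subclade divergence targets (proportions).

    Midpoints of the observed between-subclade ranges: close pairs I-II
    (0.65-1.72%) and III-IV (1.37-1.88%) at 1.2% and 1.6%, all cross pairs
    (2.97-4.22%) at 3.7%.
    """
    d = np.full((4, 4), 0.037)
    np.fill_diagonal(d, 0.0)
    d[0, 1] = d[1, 0] = 0.012
    d[2, 3] = d[3, 2] = 0.016
    return d


@dataclass
class SubcladePanel:
    """Ungapped, equal-length reference sequences, one per subclade."""

    labels: tuple[str, ...]
    references: dict[str, str]
    divergence_matrix: np.ndarray  # requested targets

    def __post_init__(self) -> None:
        lengths = {len(self.references[l]) for l in self.labels}
        if len(lengths) > 1:
            raise ValueError("reference sequences must share one length")

    @property
    def length(self) -> int:
        return len(self.references[self.labels[0]])

    def realized_divergence(self) -> np.ndarray:
        k = len(self.labels)
        out = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                d = p_distance_pair(
                    self.references[self.labels[i]], self.references[self.labels[j]]
                ).distance
                out[i, j] = out[j, i] = d
        return out

    def as_matrix(self) -> np.ndarray:
        return np.vstack(
            [
                np.frombuffer(self.references[l].encode("ascii"), dtype=np.uint8)
                for l in self.labels
            ]
        )


def _validate_divergence_matrix(dmat: np.ndarray) -> np.ndarray:
    dmat = np.asarray(dmat, dtype=float)
    k = dmat.shape[0]
    if dmat.shape != (k, k) or k < 1:
        raise ValueError("divergence matrix must be square")
    if not np.allclose(dmat, dmat.T, atol=1e-12):
        raise ValueError("divergence matrix must be symmetric")
    if np.any(np.diag(dmat) != 0):
        raise ValueError("divergence matrix diagonal must be zero")
    if dmat.min() < 0 or dmat.max() > 0.75:
        raise ValueError("divergence entries must lie in [0, 0.75]")
    return dmat


def _fit_edges(dmat: np.ndarray, labels: Sequence[str]):
    """Fit an unrooted tree's edge lengths to the requested divergences.

    Returns (edges, edge_lengths) where each edge is (parent_key, child_key)
    over a rooted traversal order and lengths solve the path system by
    non-negative least squares.  Import is deferred to avoid a cycle with
    the tree module.
    """
    from .distances import DistanceMatrix
    from .tree import nj_tree

    k = len(labels)
    n_pairs = k * (k - 1) // 2
    if k == 2:
        # single edge between the two references
        return [("__root__", labels[0]), ("__root__", labels[1])], np.array(
            [dmat[0, 1] / 2.0, dmat[0, 1] / 2.0]
        )
    dm = DistanceMatrix(ids=list(labels), d=dmat, m=np.ones((k, k), dtype=np.int64))
    tree = nj_tree(dm)

    # enumerate edges by rooted traversal from the seed node
    edges: list[tuple[int, int]] = []
    node_index: dict[int, int] = {}
    leaf_of: dict[int, str] = {}

    def idx(node) -> int:
        key = id(node)
        if key not in node_index:
            node_index[key] = len(node_index)
        return node_index[key]

    for node in tree.preorder_node_iter():
        i = idx(node)
        if node.taxon is not None:
            leaf_of[i] = node.taxon.label
        if node.parent_node is not None:
            edges.append((idx(node.parent_node), i))

    # path/edge incidence matrix over leaf pairs
    leaves = {v: i for i, v in leaf_of.items()}
    # ancestor chains
    parents = {c: p for p, c in edges}

    def chain(i: int) -> list[int]:
        out = [i]
        while out[-1] in parents:
            out.append(parents[out[-1]])
        return out

    rows = []
    targets = []
    pair_edges = []
    label_list = list(labels)
    for a in range(k):
        for b in range(a + 1, k):
            ca, cb = chain(leaves[label_list[a]]), chain(leaves[label_list[b]])
            sa, sb = set(ca), set(cb)
            path_nodes = [x for x in ca if x not in sb] + [x for x in cb if x not in sa]
            row = np.zeros(len(edges))
            for ei, (p, c) in enumerate(edges):
                if c in path_nodes:
                    row[ei] = 1.0
            rows.append(row)
            targets.append(dmat[a, b])
            pair_edges.append((label_list[a], label_list[b]))
    A = np.vstack(rows)
    x, _ = optimize.nnls(A, np.array(targets))
    fitted = A @ x
    for (la, lb), want, got in zip(pair_edges, targets, fitted):
        if want > 0 and abs(got - want) > 0.2 * want:
            raise InfeasibleDivergenceError(
                f"divergences are not tree-additive within 20%: pair ({la}, {lb}) "
                f"requested {want:.4f}, best fit {got:.4f}; adjust the matrix "
                "toward an additive configuration (e.g. equal cross-pair values)"
            )
        if want == 0 and got > 1e-9:
            raise InfeasibleDivergenceError(
                f"pair ({la}, {lb}) requested 0 but fit {got:.4f}"
            )
    named_edges = [(p, leaf_of.get(c, f"__n{c}__")) for p, c in edges]
    return list(zip(edges, named_edges)), x


def simulate_references(
    L: int,
    divergence_matrix: np.ndarray | Sequence[Sequence[float]] | None = None,
    seed: int = 0,
    labels: Sequence[str] | None = None,
) -> SubcladePanel:
    """Generate a panel of reference sequences approximating target divergences.

    A random ancestor of length ``L`` is evolved along a tree fitted to the
    requested divergence matrix; each edge mutates a disjoint set of columns
    (to a different base), so pairwise divergences are exact up to the
    rounding of edge lengths to whole sites.  Deterministic given ``seed``.
    """
    if L < 100:
        raise ValueError("reference length L must be >= 100")
    if divergence_matrix is None:
        divergence_matrix = default_divergence_matrix()
    dmat = _validate_divergence_matrix(np.asarray(divergence_matrix, dtype=float))
    k = dmat.shape[0]
    if labels is None:
        labels = tuple(_ROMAN[:k]) if k <= len(_ROMAN) else tuple(
            f"G{i+1}" for i in range(k)
        )
    labels = tuple(labels)
    if len(labels) != k:
        raise ValueError("labels must match the divergence matrix dimension")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EF5]))
    ancestor = rng.choice(_BASES, size=L)

    if k == 1 or dmat.max() == 0.0:
        seq = ancestor.tobytes().decode("ascii")
        return SubcladePanel(
            labels=labels,
            references={l: seq for l in labels},
            divergence_matrix=dmat,
        )

    edge_info, lengths = _fit_edges(dmat, labels)
    counts = [int(round(x * L)) for x in lengths]
    if sum(counts) > L:
        raise InfeasibleDivergenceError(
            f"requested divergences need {sum(counts)} mutated columns but L={L}"
        )
    site_perm = rng.permutation(L)
    # walk edges in traversal order, accumulating sequences per node
    seqs: dict[int, np.ndarray] = {}
    offset = 0
    if isinstance(edge_info[0][0], tuple):  # k >= 3 path: ((p, c), (pname, cname))
        edges = [e for e, _ in edge_info]
        root = edges[0][0]
        seqs[root] = ancestor.copy()
        # leaf names
        from_nodes = {}
        for (p, c), (_, cname) in zip(edges, [ne for _, ne in edge_info]):
            sites = site_perm[offset : offset + counts[edges.index((p, c))]]
            offset += len(sites)
            child = seqs[p].copy()
            if len(sites):
                shifts = rng.integers(1, 4, size=len(sites))
                base_idx = np.searchsorted(_BASES, child[sites])
                child[sites] = _BASES[(base_idx + shifts) % 4]
            seqs[c] = child
            from_nodes[c] = cname
        references = {
            cname: seqs[c].tobytes().decode("ascii")
            for c, cname in from_nodes.items()
            if not cname.startswith("__n")
        }
    else:  # k == 2: two pendant edges from a virtual root
        references = {}
        for (root, lab), cnt in zip(edge_info, counts):
            sites = site_perm[offset : offset + cnt]
            offset += cnt
            child = ancestor.copy()
            if len(sites):
                shifts = rng.integers(1, 4, size=len(sites))
                base_idx = np.searchsorted(_BASES, child[sites])
                child[sites] = _BASES[(base_idx + shifts) % 4]
            references[lab] = child.tobytes().decode("ascii")

    missing = [l for l in labels if l not in references]
    if missing:
        raise RuntimeError(f"internal error: no sequence generated for {missing}")
    panel = SubcladePanel(
        labels=labels, references=references, divergence_matrix=dmat
    )
    realized = panel.realized_divergence()
    for i in range(k):
        for j in range(i + 1, k):
            want = dmat[i, j]
            got = realized[i, j]
            if want == 0.0:
                ok = got == 0.0
            else:
                ok = abs(got - want) <= 0.2 * want
            if not ok:
                raise InfeasibleDivergenceError(
                    f"realized divergence {got:.4f} for pair "
                    f"({labels[i]}, {labels[j]}) misses target {want:.4f} by more "
                    f"than 20%; increase L (currently {L}) or relax the targets"
                )
    return panel


@dataclass(frozen=True)
class Clone:
    clone_id: str
    residues: str
    truth_label: str


@dataclass
class CapsuleLibrary:
    """One simulated egg capsule's clone set with ground-truth labels."""

    capsule_id: str
    host: str
    true_incidence: float
    subclade_mixture: dict[str, float]
    clones: list[Clone] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = sum(self.subclade_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"subclade mixture sums to {total}, not 1")
        ids = [c.clone_id for c in self.clones]
        if len(set(ids)) != len(ids):
            raise ValueError("clone ids are not unique")

    def non_target_count(self) -> int:
        return sum(1 for c in self.clones if c.truth_label == NON_TARGET)


def _capsule_rng(capsule_id: str, seed: int) -> np.random.Generator:
    # substream derived by hashing (capsule_id, seed): reproducible and
    # independent of capsule generation order
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), zlib.crc32(capsule_id.encode())])
    )


def _non_target_template(panel: SubcladePanel, rng: np.random.Generator) -> np.ndarray:
    """A contaminant sequence at >= NON_TARGET_MIN_DIVERGENCE from every reference."""
    refs = panel.as_matrix()
    L = panel.length
    max_div = float(panel.realized_divergence().max()) if len(panel.labels) > 1 else 0.0
    k_sites = min(L, math.ceil(L * (NON_TARGET_MIN_DIVERGENCE + max_div + 0.05)))
    template = refs[0].copy()
    for _ in range(20):
        sites = rng.choice(L, size=k_sites, replace=False)
        cand = refs[0].copy()
        shifts = rng.integers(1, 4, size=k_sites)
        base_idx = np.searchsorted(_BASES, cand[sites])
        cand[sites] = _BASES[(base_idx + shifts) % 4]
        dists = (cand[None, :] != refs).mean(axis=1)
        if dists.min() >= NON_TARGET_MIN_DIVERGENCE:
            return cand
        k_sites = min(L, k_sites + max(1, L // 20))
    raise RuntimeError("could not place a contaminant >=10% from all references")


def simulate_capsule_library(
    panel: SubcladePanel,
    host: str,
    n_clones: int,
    q: float,
    subclade_mixture: Mapping[str, float],
    error_rate: float = 0.0,
    seed: int = 0,
    capsule_id: str = "CAP1",
    q_concentration: float | None = None,
) -> CapsuleLibrary:
    """Simulate one capsule's clone library.

    Each clone is independently a contaminant with probability ``q``; target
    clones copy a mixture-chosen reference and receive independent per-site
    substitutions at ``error_rate`` (uniform over the three alternative
    bases).  ``q_concentration``, when set, draws the capsule's effective
    incidence from Beta(q*c, (1-q)*c) — per-capsule overdispersion, off by
    default because the detection model assumes equal incidence everywhere.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must be in [0, 1]")
    if not 0.0 <= error_rate <= 0.05:
        raise ValueError("error_rate must be in [0, 0.05]")
    mixture = dict(subclade_mixture)
    unknown = set(mixture) - set(panel.labels)
    if unknown:
        raise ValueError(f"mixture labels not in panel: {sorted(unknown)}")
    probs = np.array([mixture.get(l, 0.0) for l in panel.labels], dtype=float)
    if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("mixture must be a probability vector summing to 1")

    rng = _capsule_rng(capsule_id, seed)
    q_eff = q
    if q_concentration is not None and 0.0 < q < 1.0:
        q_eff = float(
            rng.beta(q * q_concentration, (1.0 - q) * q_concentration)
        )

    L = panel.length
    refs = panel.as_matrix()
    is_nt = rng.random(n_clones) < q_eff
    label_idx = rng.choice(len(panel.labels), size=n_clones, p=probs)
    clones_arr = refs[label_idx].copy()
    if error_rate > 0:
        err_mask = rng.random((n_clones, L)) < error_rate
        n_err = int(err_mask.sum())
        if n_err:
            shifts = rng.integers(1, 4, size=n_err)
            base_idx = np.searchsorted(_BASES, clones_arr[err_mask])
            clones_arr[err_mask] = _BASES[(base_idx + shifts) % 4]
    if is_nt.any():
        nt = _non_target_template(panel, rng)
        clones_arr[is_nt] = nt

    clones = []
    for i in range(n_clones):
        label = NON_TARGET if is_nt[i] else panel.labels[label_idx[i]]
        clones.append(
            Clone(
                clone_id=f"{capsule_id}_c{i + 1:03d}",
                residues=clones_arr[i].tobytes().decode("ascii"),
                truth_label=label,
            )
        )
    return CapsuleLibrary(
        capsule_id=capsule_id,
        host=host,
        true_incidence=q_eff,
        subclade_mixture={l: float(mixture.get(l, 0.0)) for l in panel.labels},
        clones=clones,
    )


@dataclass(frozen=True)
class DesignRow:
    """One site's sampling design: capsules per site, clones per capsule."""

    host: str
    site_code: str
    n_capsules: int
    clones_per_capsule: int
    q: float
    mixture: Mapping[str, float]


@dataclass
class SyntheticSurvey:
    manifest: SampleManifest
    capsules: list[CapsuleLibrary]
    alignment: AlignedSeqSet
    truth: pd.DataFrame  # clone_id, capsule_id, site_code, host, truth_label
    panel: SubcladePanel
    params: dict

    def truth_map(self) -> dict[str, tuple[str, str]]:
        """clone_id -> (host, site_code), as needed by composition tables."""
        return {
            r.clone_id: (r.host, r.site_code) for r in self.truth.itertuples()
        }

    def per_host_clone_counts(self) -> dict[str, int]:
        return self.truth.groupby("host").size().to_dict()


def survey_design(q: float = 0.0) -> list[DesignRow]:
    """Default survey design shaped like the study: per-host clone totals 85/27/9/5.

    Host-subclade associations follow the observed pattern: subclade I
    (A. maculatum), II (A. gracile), III (A. maculatum and L. aurora),
    IV (L. sylvatica).  ``q`` defaults to 0 — no contaminant was observed in
    the real survey; tests raise it explicitly.
    """
    return [
        DesignRow("A. maculatum", "AM-NS", 9, 5, q, {"I": 0.8, "III": 0.2}),
        DesignRow("A. maculatum", "AM-NJ", 8, 5, q, {"I": 0.8, "III": 0.2}),
        DesignRow("A. gracile", "AG-BC", 3, 9, q, {"II": 1.0}),
        DesignRow("L. sylvatica", "LS-NS", 3, 3, q, {"IV": 1.0}),
        DesignRow("L. aurora", "LA-BC", 1, 5, q, {"III": 1.0}),
    ]


def simulate_survey(
    panel: SubcladePanel,
    design: Sequence[DesignRow],
    error_rate: float = 0.002,
    seed: int = 0,
) -> SyntheticSurvey:
    """Simulate a full survey: manifest, capsules, pooled alignment, truth table."""
    if not design:
        raise ValueError("design is empty")
    codes = [row.site_code for row in design]
    if len(set(codes)) != len(codes):
        raise ValueError(f"duplicate site codes in design: {codes}")

    site_rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 0xA11]))
    manifest_rows = []
    capsules: list[CapsuleLibrary] = []
    truth_records = []
    ids: list[str] = []
    rows: list[str] = []
    for row in design:
        site_accessions: list[str] = []
        for ci in range(row.n_capsules):
            cap_id = f"{row.site_code}-cap{ci + 1:02d}"
            lib = simulate_capsule_library(
                panel,
                host=row.host,
                n_clones=row.clones_per_capsule,
                q=row.q,
                subclade_mixture=row.mixture,
                error_rate=error_rate,
                seed=seed,
                capsule_id=cap_id,
            )
            capsules.append(lib)
            for clone in lib.clones:
                ids.append(clone.clone_id)
                rows.append(clone.residues)
                site_accessions.append(clone.clone_id)
                truth_records.append(
                    {
                        "clone_id": clone.clone_id,
                        "capsule_id": cap_id,
                        "site_code": row.site_code,
                        "host": row.host,
                        "truth_label": clone.truth_label,
                    }
                )
        lon = float(np.round(site_rng.uniform(-130.0, -60.0), 3))
        lat = float(np.round(site_rng.uniform(30.0, 50.0), 3))
        manifest_rows.append(
            SampleRow(
                location=f"Synthetic pond {row.site_code}",
                code=row.site_code,
                lon=lon,
                lat=lat,
                date="2012",
                sample_type="ES",
                host=row.host,
                accessions=tuple(site_accessions),
            )
        )

    params = {
        "seed": int(seed),
        "error_rate": error_rate,
        "panel_labels": list(panel.labels),
        "panel_length": panel.length,
        "divergence_matrix": np.asarray(panel.divergence_matrix).tolist(),
        "design": [
            {
                "host": r.host,
                "site_code": r.site_code,
                "n_capsules": r.n_capsules,
                "clones_per_capsule": r.clones_per_capsule,
                "q": r.q,
                "mixture": dict(r.mixture),
            }
            for r in design
        ],
    }
    return SyntheticSurvey(
        manifest=SampleManifest(rows=manifest_rows),
        capsules=capsules,
        alignment=AlignedSeqSet(ids=ids, rows=rows),
        truth=pd.DataFrame(truth_records),
        panel=panel,
        params=params,
    )


def write_survey(survey: SyntheticSurvey, out_dir: str | Path) -> dict[str, Path]:
    """Write survey artifacts: FASTA, manifest TSV, truth TSV, parameter JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "survey.fasta",
        "manifest": out / "manifest.tsv",
        "truth": out / "truth.tsv",
        "params": out / "params.json",
    }
    write_aligned_fasta(survey.alignment, paths["fasta"])
    write_manifest(survey.manifest, paths["manifest"])
    survey.truth.to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["params"], "w", encoding="utf-8") as fh:
        json.dump(survey.params, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
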