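"""ceRNA (sponge) network construction and interrogation.

The construction composes three filters, in order, over differentially
expressed transcripts only:

1. negative miRNA-target coexpression — a miRNA->target pair survives iff
   it is annotated in the target table, both members are DE, and their
   Spearman rank correlation is < -0.7 (strict);
2. positive lncRNA-mRNA coexpression — a (lncRNA, mRNA) pair is a sponge
   candidate iff its Pearson correlation is > 0.9 (strict) and at least one
   miRNA is linked to both by surviving negative pairs;
3. shared-sponge significance — an upper-tail hypergeometric test on the
   number of shared miRNAs; pairs with p < 0.05 (strict) are kept.

The hypergeometric counts are, by default, taken *after* the negative-
correlation filter: K = miRNAs sponged by the lncRNA, n = miRNAs targeting
the mRNA, k = shared, N = universe of eligible miRNAs (see
``universe_policy``). No correction is applied across sponge pairs by
default (raw p < alpha), with BH available as an option.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .simulate import SampleDesign

__all__ = [
    "rank_correlation",
    "pearson_correlation",
    "select_negative_target_pairs",
    "candidate_sponge_pairs",
    "sponge_test",
    "build_network",
    "extract_subnetwork",
    "ora_enrichment",
    "network_summary",
    "GeneSet",
    "NetworkThresholds",
]

log = logging.getLogger(__name__)

TARGET_CLASSES = ("lncRNA", "mRNA")


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")


@dataclass(frozen=True)
class NetworkThresholds:
    """The three printed cutoffs; all applied as strict inequalities."""

    scc: float = -0.7
    pcc: float = 0.9
    alpha: float = 0.05

    def __post_init__(self):
        if not -1.0 <= self.scc < 0.0:
            raise ValueError("scc threshold must lie in [-1, 0)")
        if not 0.0 < self.pcc <= 1.0:
            raise ValueError("pcc threshold must lie in (0, 1]")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")


def _check_vectors(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("correlation needs >= 3 points")
    return x, y


def rank_correlation(x, y) -> float:
    """Spearman rank correlation with average (mid-rank) ties.

    Returns NaN when either vector is constant (rank correlation is then
    undefined); callers exclude such pairs from candidacy.
    """
    x, y = _check_vectors(x, y)
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def pearson_correlation(x, y) -> float:
    """Product-moment correlation; NaN for constant input."""
    x, y = _check_vectors(x, y)
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def _align(matrix: pd.DataFrame, samples: Sequence[str]) -> pd.DataFrame:
    missing = [s for s in samples if s not in matrix.columns]
    if missing:
        raise ValueError(f"matrix lacks sample columns: {missing}")
    return matrix[list(samples)]


def select_negative_target_pairs(
    mir_matrix: pd.DataFrame,
    other_matrix: pd.DataFrame,
    targets: pd.DataFrame,
    de_mir: set[str] | Iterable[str],
    de_other: set[str] | Iterable[str],
    scc_thresh: float = -0.7,
    target_class: str | None = None,
) -> pd.DataFrame:
    """Annotated miRNA->target pairs that are DE on both ends and SCC < thresh.

    ``targets`` has columns (mirna_id, target_id, target_class); rows whose
    target class does not match ``target_class`` (when given) are ignored.
    Matrices must share identical sample columns in identical order.
    Undefined correlations (constant vectors) never survive.
    """
    if list(mir_matrix.columns) != list(other_matrix.columns):
        raise ValueError("matrices must share the same sample columns in the same order")
    de_mir = set(de_mir)
    de_other = set(de_other)
    sub = targets
    if target_class is not None:
        sub = targets[targets["target_class"] == target_class]
    rows = []
    for mir, tgt in sub[["mirna_id", "target_id"]].itertuples(index=False):
        if mir not in de_mir or tgt not in de_other:
            continue
        if mir not in mir_matrix.index or tgt not in other_matrix.index:
            continue
        scc = rank_correlation(
            mir_matrix.loc[mir].to_numpy(), other_matrix.loc[tgt].to_numpy()
        )
        if not math.isnan(scc) and scc < scc_thresh:
            rows.append((mir, tgt, scc))
    out = pd.DataFrame(rows, columns=["mirna_id", "target_id", "scc"])
    return out.sort_values(["mirna_id", "target_id"], ignore_index=True)


def candidate_sponge_pairs(
    lnc_matrix: pd.DataFrame,
    mrna_matrix: pd.DataFrame,
    neg_lnc_pairs: pd.DataFrame,
    neg_mrna_pairs: pd.DataFrame,
    pcc_thresh: float = 0.9,
) -> pd.DataFrame:
    """(lncRNA, mRNA) pairs with PCC > thresh and >= 1 shared sponged miRNA.

    Shared miRNAs are taken from the surviving negative pairs: a miRNA
    counts as shared iff it is negatively coexpressed with (and targets)
    both members. Returns columns (lnc_id, mrna_id, pcc, shared_mirnas)
    with shared_mirnas as a frozenset.
    """
    if list(lnc_matrix.columns) != list(mrna_matrix.columns):
        raise ValueError("matrices must share the same sample columns in the same order")
    mir_to_lnc: dict[str, set[str]] = {}
    for mir, lnc in neg_lnc_pairs[["mirna_id", "target_id"]].itertuples(index=False):
        mir_to_lnc.setdefault(mir, set()).add(lnc)
    mir_to_mrna: dict[str, set[str]] = {}
    for mir, mrna in neg_mrna_pairs[["mirna_id", "target_id"]].itertuples(index=False):
        mir_to_mrna.setdefault(mir, set()).add(mrna)
    shared: dict[tuple[str, str], set[str]] = {}
    for mir in set(mir_to_lnc) & set(mir_to_mrna):
        for lnc in mir_to_lnc[mir]:
            for mrna in mir_to_mrna[mir]:
                shared.setdefault((lnc, mrna), set()).add(mir)
    rows = []
    for (lnc, mrna), mirs in sorted(shared.items()):
        pcc = pearson_correlation(
            lnc_matrix.loc[lnc].to_numpy(), mrna_matrix.loc[mrna].to_numpy()
        )
        if not math.isnan(pcc) and pcc > pcc_thresh:
            rows.append((lnc, mrna, pcc, frozenset(mirs)))
    return pd.DataFrame(rows, columns=["lnc_id", "mrna_id", "pcc", "shared_mirnas"])


def sponge_test(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts shared miRNAs when n are drawn from a universe of N of which K
    are sponged by the lncRNA. Computed with exact integer combinatorics
    (a single float division at the end), so it matches enumeration to
    machine precision for any feasible (k, K, n, N).
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer")
    k, K, n, N = int(k), int(K), int(n), int(N)
    if K > N or n > N:
        raise ValueError("K and n cannot exceed N")
    if k > min(K, n):
        raise ValueError("k cannot exceed min(K, n)")
    if K < 1 or n < 1:
        raise ValueError("K and n must be >= 1")
    if k == 0:
        return 1.0
    num = sum(math.comb(K, i) * math.comb(N - K, n - i) for i in range(k, min(K, n) + 1))
    return num / math.comb(N, n)


def _universe(
    policy: str,
    targets: pd.DataFrame,
    mir_matrix: pd.DataFrame,
    de_mir: set[str],
) -> set[str]:
    table_mirs = set(targets["mirna_id"])
    if policy == "de_targets":
        return table_mirs & de_mir
    if policy == "table":
        return table_mirs
    if policy == "matrix":
        return set(mir_matrix.index)
    raise ValueError(f"unknown universe_policy {policy!r}")


def build_network(
    lnc_matrix: pd.DataFrame,
    mir_matrix: pd.DataFrame,
    mrna_matrix: pd.DataFrame,
    design: Sequence[SampleDesign],
    targets: pd.DataFrame,
    de_lnc: pd.DataFrame,
    de_mir: pd.DataFrame,
    de_mrna: pd.DataFrame,
    thresholds: NetworkThresholds = NetworkThresholds(),
    universe_policy: str = "de_targets",
    count_mode: str = "postfilter",
    adjust_sponge_p: bool = False,
) -> nx.Graph:
    """Compose the three ceRNA filters into a typed network.

    ``de_*`` are frames with an ``is_de`` boolean column indexed by
    transcript id (as produced by :func:`spongenet.diffexpr.de_table`).
    ``count_mode`` chooses whether K/n/k count miRNAs after the negative-
    correlation filter (default) or straight from the annotated target
    table restricted to DE miRNAs ("prefilter"). Nodes carry ``node_type``
    and edges ``edge_type`` in {mir_lnc, mir_mrna, lnc_mrna}.
    """
    samples = [s.sample_id for s in design]
    # Correlations are computed on log2(x + 1): abundances are log-normal
    # and product-moment correlation on the raw scale is attenuated by
    # skew. Spearman is invariant to the transform; only the PCC filter
    # sees it.
    lnc_m = np.log2(_align(lnc_matrix, samples) + 1.0)
    mir_m = np.log2(_align(mir_matrix, samples) + 1.0)
    mrna_m = np.log2(_align(mrna_matrix, samples) + 1.0)
    de_lnc_ids = set(de_lnc.index[de_lnc["is_de"]])
    de_mir_ids = set(de_mir.index[de_mir["is_de"]])
    de_mrna_ids = set(de_mrna.index[de_mrna["is_de"]])

    net = nx.Graph()
    if not (de_lnc_ids and de_mir_ids and de_mrna_ids):
        log.warning("at least one RNA class has no DE transcripts; returning empty network")
        return net

    neg_lnc = select_negative_target_pairs(
        mir_m, lnc_m, targets, de_mir_ids, de_lnc_ids, thresholds.scc, "lncRNA"
    )
    neg_mrna = select_negative_target_pairs(
        mir_m, mrna_m, targets, de_mir_ids, de_mrna_ids, thresholds.scc, "mRNA"
    )
    cand = candidate_sponge_pairs(lnc_m, mrna_m, neg_lnc, neg_mrna, thresholds.pcc)

    universe = _universe(universe_policy, targets, mir_m, de_mir_ids)
    N = len(universe)
    if count_mode == "postfilter":
        per_lnc = neg_lnc.groupby("target_id")["mirna_id"].agg(set).to_dict()
        per_mrna = neg_mrna.groupby("target_id")["mirna_id"].agg(set).to_dict()
    elif count_mode == "prefilter":
        t_lnc = targets[targets["target_class"] == "lncRNA"]
        t_mrna = targets[targets["target_class"] == "mRNA"]
        per_lnc = (
            t_lnc[t_lnc["mirna_id"].isin(de_mir_ids)]
            .groupby("target_id")["mirna_id"].agg(set).to_dict()
        )
        per_mrna = (
            t_mrna[t_mrna["mirna_id"].isin(de_mir_ids)]
            .groupby("target_id")["mirna_id"].agg(set).to_dict()
        )
    else:
        raise ValueError(f"unknown count_mode {count_mode!r}")

    records = []
    for lnc, mrna, pcc, shared in cand.itertuples(index=False):
        K = len(per_lnc.get(lnc, set()) & universe)
        n = len(per_mrna.get(mrna, set()) & universe)
        shared_u = set(shared) & universe
        k = len(shared_u)
        if N == 0 or K == 0 or n == 0:
            continue
        p = sponge_test(min(k, min(K, n)), K, n, N)
        records.append((lnc, mrna, pcc, frozenset(shared), k, K, n, N, p))
    pvals = [r[-1] for r in records]
    crit = bh_adjust(pvals) if (adjust_sponge_p and pvals) else pvals

    neg_lookup_lnc = {
        (m, t): s for m, t, s in neg_lnc.itertuples(index=False)
    }
    neg_lookup_mrna = {
        (m, t): s for m, t, s in neg_mrna.itertuples(index=False)
    }
    for rec, c in zip(records, crit):
        lnc, mrna, pcc, shared, k, K, n, N_, p = rec
        if not c < thresholds.alpha:
            continue
        net.add_node(lnc, node_type="lncRNA")
        net.add_node(mrna, node_type="mRNA")
        net.add_edge(
            lnc,
            mrna,
            edge_type="lnc_mrna",
            statistic=pcc,
            pvalue=p,
            shared_mirnas=";".join(sorted(shared)),
            k=k,
            K=K,
            n=n,
            N=N_,
        )
        for mir in sorted(shared):
            net.add_node(mir, node_type="miRNA")
            net.add_edge(mir, lnc, edge_type="mir_lnc", statistic=neg_lookup_lnc[(mir, lnc)])
            net.add_edge(mir, mrna, edge_type="mir_mrna", statistic=neg_lookup_mrna[(mir, mrna)])
    return net


def sponge_pairs(net: nx.Graph) -> set[tuple[str, str]]:
    """The (lnc_id, mrna_id) edges of the network, lncRNA first."""
    out = set()
    for u, v, d in net.edges(data=True):
        if d.get("edge_type") == "lnc_mrna":
            if net.nodes[u]["node_type"] == "lncRNA":
                out.add((u, v))
            else:
                out.add((v, u))
    return out


def extract_subnetwork(net: nx.Graph, genes: GeneSet) -> nx.Graph:
    """Sub-network of sponge edges whose mRNA belongs to a gene set.

    Keeps every lnc_mrna edge with mRNA in ``genes`` plus the incident
    lncRNA/miRNA nodes and their surviving negative edges. Unknown ids in
    the set are ignored (a count is logged).
    """
    known = {n for n, d in net.nodes(data=True) if d.get("node_type") == "mRNA"}
    unknown = len(set(genes.members) - known)
    if unknown:
        log.info("extract_subnetwork: %d gene-set ids not in network", unknown)
    sub = nx.Graph()
    for u, v, d in net.edges(data=True):
        if d.get("edge_type") != "lnc_mrna":
            continue
        lnc, mrna = (u, v) if net.nodes[u]["node_type"] == "lncRNA" else (v, u)
        if mrna not in genes.members:
            continue
        sub.add_node(lnc, **net.nodes[lnc])
        sub.add_node(mrna, **net.nodes[mrna])
        sub.add_edge(lnc, mrna, **d)
        for mir in d["shared_mirnas"].split(";") if d["shared_mirnas"] else []:
            sub.add_node(mir, **net.nodes[mir])
            sub.add_edge(mir, lnc, **net.edges[mir, lnc])
            sub.add_edge(mir, mrna, **net.edges[mir, mrna])
    return sub


def ora_enrichment(
    hits: Iterable[str],
    sets: Sequence[GeneSet],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Over-representation of ``hits`` in each gene set (hypergeometric + BH).

    Each set is intersected with the universe before testing; the p-value
    is the upper tail P(overlap >= k) and the FDR is BH across the sets.
    """
    hits = set(hits)
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    rows = []
    for gs in sets:
        members = set(gs.members) & universe
        K, n, N = len(members), len(hits), len(universe)
        k = len(members & hits)
        p = 1.0 if (K == 0 or n == 0) else sponge_test(k, K, n, N)
        rows.append((gs.name, k, K, n, N, p))
    out = pd.DataFrame(rows, columns=["set_name", "k", "K", "n", "N", "pvalue"])
    out["fdr"] = bh_adjust(out["pvalue"].to_numpy()) if len(out) else []
    return out


def network_summary(net: nx.Graph) -> dict:
    """Headline counts: sponge pairs, nodes by type, per-mRNA regulators.

    Per mRNA: the number of distinct lncRNA partners and the distinct union
    of miRNAs shared across its sponge edges (the '36 lncRNAs and 5 miRNAs
    regulate IGF1' style of summary).
    """
    by_type = {"lncRNA": 0, "miRNA": 0, "mRNA": 0}
    for _, d in net.nodes(data=True):
        by_type[d["node_type"]] += 1
    per_mrna: dict[str, dict[str, set]] = {}
    n_pairs = 0
    for u, v, d in net.edges(data=True):
        if d.get("edge_type") != "lnc_mrna":
            continue
        n_pairs += 1
        lnc, mrna = (u, v) if net.nodes[u]["node_type"] == "lncRNA" else (v, u)
        rec = per_mrna.setdefault(mrna, {"lncRNAs": set(), "miRNAs": set()})
        rec["lncRNAs"].add(lnc)
        if d["shared_mirnas"]:
            rec["miRNAs"].update(d["shared_mirnas"].split(";"))
    return {
        "n_lnc_mrna_pairs": n_pairs,
        "nodes_by_type": by_type,
        "per_mrna": {
            m: {"n_lncRNAs": len(r["lncRNAs"]), "n_miRNAs": len(r["miRNAs"])}
            for m, r in sorted(per_mrna.items())
        },
    }
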