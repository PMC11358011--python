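"""Cross-species set intersection and the core-signature Venn partition.

Rat banding-model DEGs are mapped through a 1:1 ortholog map into the human
namespace, intersected with two human gene lists (a right-heart cohort screen
and a left-heart-failure meta-analysis list), and partitioned into four
disjoint Venn classes.  Overlaps are tested with a one-sided (enrichment)
hypergeometric upper tail -- Fisher's exact test for over-representation --
against an explicitly supplied expressed-gene universe.  The core signature
can be split into ECM/secreted vs non-ECM components with an induced
interaction subgraph filtered at a confidence-score cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd
from scipy import stats


@dataclass
class FisherResult:
    universe: int
    n_a: int
    n_b: int
    overlap: int
    expected: float
    p: float

    def as_dict(self) -> dict:
        return {
            "universe": self.universe, "n_a": self.n_a, "n_b": self.n_b,
            "overlap": self.overlap, "expected": self.expected, "p": self.p,
        }


def fisher_overlap(universe_size: int, set_a, set_b,
                   overlap: int | None = None) -> FisherResult:
    """One-sided hypergeometric upper-tail p for the overlap of two sets.

    ``set_a`` and ``set_b`` may be gene sets (the overlap is computed) or
    integers giving set sizes, in which case ``overlap`` must be supplied.
    p = P(X >= k) for X ~ Hypergeom(N, nA, nB).
    """
    if isinstance(set_a, int) and isinstance(set_b, int):
        n_a, n_b = set_a, set_b
        if overlap is None:
            raise ValueError("overlap must be given with integer set sizes")
        k = overlap
    else:
        set_a, set_b = set(set_a), set(set_b)
        n_a, n_b = len(set_a), len(set_b)
        k = len(set_a & set_b)
    if n_a > universe_size or n_b > universe_size:
        raise ValueError("sets exceed the universe")
    if k > min(n_a, n_b):
        raise ValueError("overlap exceeds the smaller set")
    expected = n_a * n_b / universe_size
    p = float(stats.hypergeom.sf(k - 1, universe_size, n_a, n_b))
    return FisherResult(universe=universe_size, n_a=n_a, n_b=n_b,
                        overlap=k, expected=expected, p=min(p, 1.0))


# ------------------------------------------------------------- ortholog map

def resolve_orthologs(pairs: pd.DataFrame) -> tuple[dict[str, str], pd.DataFrame]:
    """Reduce an ortholog pair table to a 1:1 map.

    ``pairs`` has columns ``rat_gene`` and ``human_gene``; duplicates on
    either side are resolved by keeping the lexicographically first partner.
    Returns the map and a report of dropped ambiguous pairs.
    """
    df = pairs[["rat_gene", "human_gene"]].astype(str).drop_duplicates()
    df = df.sort_values(["rat_gene", "human_gene"], kind="stable")
    kept = df.drop_duplicates("rat_gene", keep="first")
    kept = kept.drop_duplicates("human_gene", keep="first")
    dropped = df.loc[~df.index.isin(kept.index)]
    mapping = dict(zip(kept["rat_gene"], kept["human_gene"]))
    return mapping, dropped.reset_index(drop=True)


# --------------------------------------------------------- signature report

@dataclass
class SignatureReport:
    """Disjoint Venn partition of the mapped rat set against two human lists."""

    rat_only: set[str]
    rat_hctpeh_only: set[str]
    rat_hlhf_only: set[str]
    rat_hctpeh_hlhf: set[str]
    unmapped_rat: set[str]
    fisher: dict[str, FisherResult] = field(default_factory=dict)

    @property
    def core(self) -> set[str]:
        return self.rat_hctpeh_only | self.rat_hlhf_only | self.rat_hctpeh_hlhf

    def sizes(self) -> dict[str, int]:
        return {
            "rat_only": len(self.rat_only),
            "rat_hctpeh_only": len(self.rat_hctpeh_only),
            "rat_hlhf_only": len(self.rat_hlhf_only),
            "rat_hctpeh_hlhf": len(self.rat_hctpeh_hlhf),
            "core": len(self.core),
            "unmapped_rat": len(self.unmapped_rat),
        }


def build_core_signature(rat_set, hctpeh_set, hlhf_set,
                         orthologs: Mapping[str, str] | pd.DataFrame,
                         universe_size: int) -> SignatureReport:
    """Map rat genes to human orthologs and partition the Venn overlap.

    The universe is the number of genes expressed in the human baseline
    cohort; it must be supplied explicitly for the Fisher tests.
    """
    if isinstance(orthologs, pd.DataFrame):
        orthologs, _ = resolve_orthologs(orthologs)
    if not orthologs:
        raise ValueError("empty ortholog map")
    rat_set = set(rat_set)
    hctpeh = set(hctpeh_set)
    hlhf = set(hlhf_set)
    mapped = {orthologs[g] for g in rat_set if g in orthologs}
    unmapped = {g for g in rat_set if g not in orthologs}
    both = mapped & hctpeh & hlhf
    report = SignatureReport(
        rat_only=mapped - hctpeh - hlhf,
        rat_hctpeh_only=(mapped & hctpeh) - both,
        rat_hlhf_only=(mapped & hlhf) - both,
        rat_hctpeh_hlhf=both,
        unmapped_rat=unmapped,
    )
    report.fisher["rat_vs_hctpeh"] = fisher_overlap(universe_size, mapped, hctpeh)
    report.fisher["rat_vs_hlhf"] = fisher_overlap(universe_size, mapped, hlhf)
    return report


def partition_signature(core: set[str], ecm_sets: Mapping[str, set[str]],
                        edges: pd.DataFrame,
                        min_score: float = 0.4) -> dict:
    """Split the core signature into ECM/secreted vs non-ECM components.

    Genes annotated to any set in ``ecm_sets`` form the ECM component; the
    remainder is non-ECM.  ``edges`` has columns gene_a, gene_b, score; the
    induced subgraph per component keeps edges with score strictly above
    ``min_score``, drops self-loops, and treats edges as undirected.
    """
    core = set(core)
    ecm_members = set().union(*ecm_sets.values()) if ecm_sets else set()
    ecm = core & ecm_members
    non_ecm = core - ecm

    e = edges.copy()
    e = e[(e["score"] > min_score) & (e["gene_a"] != e["gene_b"])]

    def induced(component: set[str]) -> pd.DataFrame:
        sub = e[e["gene_a"].isin(component) & e["gene_b"].isin(component)]
        # canonical undirected orientation, drop duplicates
        a = sub[["gene_a", "gene_b"]].min(axis=1)
        b = sub[["gene_a", "gene_b"]].max(axis=1)
        out = pd.DataFrame({"gene_a": a, "gene_b": b, "score": sub["score"]})
        return (out.sort_values(["gene_a", "gene_b"], kind="stable")
                   .drop_duplicates(["gene_a", "gene_b"]).reset_index(drop=True))

    return {
        "ecm_component": ecm,
        "non_ecm": non_ecm,
        "ecm_edges": induced(ecm),
        "non_ecm_edges": induced(non_ecm),
    }
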