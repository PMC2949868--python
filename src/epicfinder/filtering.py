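"""Gene-family selection: duplication inference and coverage/paralogy rules.

Families are kept only if every required clade is represented and no gene
duplication sits at the root (MRCA) of a required clade.  Duplications are
called with the species-overlap criterion: an internal node is a duplication
node iff at least two of its child subtrees share a species.  A duplication
confined to a single species inside a clade does not disqualify the family
(the "isolated species" exemption).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Set

import dendropy

from epicfinder.model import GeneTree, HomologyHit, TaxonomyMap


@dataclass
class DuplicationCall:
    """Verdict for one internal node."""

    node_id: str
    duplicated: bool
    offending_species: Set[str] = field(default_factory=set)
    offending_clades: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.duplicated != bool(self.offending_clades):
            raise ValueError("duplicated flag must match offending-clade set")


@dataclass
class FamilyVerdict:
    family_id: str
    retained: bool
    reasons: List[str] = field(default_factory=list)


def infer_duplications(gene_tree: GeneTree, taxonomy: TaxonomyMap) -> GeneTree:
    """Flag duplication nodes by species overlap between child subtrees.

    Attaches a :class:`DuplicationCall` to every internal node (as the
    ``duplication`` attribute) and returns the same tree.  Raises if the tree
    is unrooted or a leaf species is absent from the taxonomy map.
    """
    if not gene_tree.tree.is_rooted:
        raise ValueError("gene tree must be rooted")
    for gid, sp in gene_tree.species.items():
        if sp not in taxonomy.species_to_clade:
            raise KeyError(f"species {sp!r} (gene {gid}) not in taxonomy map")

    counter = 0
    # postorder: species set of each node computed from children
    for node in gene_tree.tree.postorder_node_iter():
        if node.is_leaf():
            node._species_set = {gene_tree.species[node.taxon.label]}
            continue
        children = node.child_nodes()
        child_sets = [c._species_set for c in children]
        node._species_set = set().union(*child_sets)
        shared: Set[str] = set()
        for i in range(len(child_sets)):
            for j in range(i + 1, len(child_sets)):
                shared |= child_sets[i] & child_sets[j]
        counter += 1
        node.duplication = DuplicationCall(
            node_id=f"n{counter}",
            duplicated=bool(shared),
            offending_species=shared,
            offending_clades={taxonomy.clade_of(s) for s in shared},
        )
    return gene_tree


def duplication_nodes(gene_tree: GeneTree) -> List[DuplicationCall]:
    """All duplication calls with ``duplicated=True`` (postorder)."""
    calls = []
    for node in gene_tree.tree.postorder_internal_node_iter():
        call = getattr(node, "duplication", None)
        if call is not None and call.duplicated:
            calls.append(call)
    return calls


def evaluate_family(
    gene_tree: GeneTree,
    taxonomy: TaxonomyMap,
    family_id: str = "",
) -> FamilyVerdict:
    """Apply the coverage + root-duplication retention rule.

    Retained iff (a) every required clade has at least one leaf, and (b) for
    each required clade the MRCA of that clade's leaves is not a duplication
    node whose offending species include more than one species of the clade.
    A duplication touching exactly one species of the clade is exempted and
    logged, not fatal.
    """
    if getattr(gene_tree.tree.seed_node, "duplication", None) is None:
        gene_tree = infer_duplications(gene_tree, taxonomy)

    reasons: List[str] = []
    retained = True
    for clade in taxonomy.required_clades:
        clade_species = set(taxonomy.species_in(clade))
        members = [
            g for g, s in gene_tree.species.items() if s in clade_species
        ]
        if not members:
            retained = False
            reasons.append(f"missing clade: {clade}")
            continue
        if len(members) == 1:
            continue  # single leaf: its "MRCA" is itself, no duplication possible
        mrca = gene_tree.mrca(members)
        call = getattr(mrca, "duplication", None)
        if call is None or not call.duplicated:
            continue
        offending_in_clade = call.offending_species & clade_species
        if len(offending_in_clade) > 1:
            retained = False
            reasons.append(
                f"duplication at root of clade {clade} "
                f"(species: {', '.join(sorted(offending_in_clade))})"
            )
        # a duplication at the clade MRCA whose offenders lie wholly outside
        # the clade reflects structure elsewhere in the tree; not this
        # clade's problem

    # log isolated single-species duplications inside required clades
    logged = set()
    for call in duplication_nodes(gene_tree):
        for clade in taxonomy.required_clades:
            inter = call.offending_species & set(taxonomy.species_in(clade))
            if len(inter) == 1:
                (sp,) = inter
                if (sp, clade) not in logged:
                    logged.add((sp, clade))
                    reasons.append(
                        f"exemption: isolated duplication of {sp} within {clade}"
                    )
    return FamilyVerdict(family_id=family_id, retained=retained, reasons=reasons)


def filter_hits(
    hits: List[HomologyHit],
    e_max: float = 1e-5,
    similarity_min: float = 0.5,
) -> List[str]:
    """Retain subjects with best e-value < ``e_max`` AND best similarity
    > ``similarity_min`` (both strict, matching "lower than" / "higher than").

    Returns sorted subject ids.
    """
    best_e: Dict[str, float] = {}
    best_sim: Dict[str, float] = {}
    for h in hits:
        best_e[h.subject_id] = min(best_e.get(h.subject_id, float("inf")), h.e_value)
        best_sim[h.subject_id] = max(best_sim.get(h.subject_id, -1.0), h.similarity)
    return sorted(
        s
        for s in best_e
        if best_e[s] < e_max and best_sim[s] > similarity_min
    )
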