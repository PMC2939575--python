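"""Model/Results front end for the intron-evolution inference.

`IntronEvolutionModel` bundles the data a study provides — gene structures,
a shared protein alignment, a rooted gene tree and species tree, and the
gene-to-species map — together with the analysis options. `fit()` runs the
whole inference (character matrix, duplication-loss reconciliation, Dollo
or Fitch ancestral states, per-branch event history, pathway summary and
expression time costs) and returns an `IntronEvolutionResults` carrying
every intermediate product plus a printable `summary()`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from . import expression_cost as cost
from .gene_models import GeneStructure, intron_position_table, parse_structures
from .intron_homology import CodonAlignment, IntronSiteMatrix, build_matrix
from .intron_events import (AncestralStates, EventHistory, PathwaySummary,
                            dollo_reconstruct, fitch_reconstruct, infer_events,
                            summarize_pathway)
from .reconcile import Reconciliation, lca_map, report_gene_losses
from .trees import RootedTree

__all__ = ["IntronEvolutionModel", "IntronEvolutionResults"]


class IntronEvolutionModel:
    """Intron gain/loss inference over a gene family on a species tree.

    Parameters
    ----------
    structures
        Gene structures (or a TSV/GFF3 path understood by
        :func:`intronevo.gene_models.parse_structures`).
    alignment
        Shared protein alignment covering the analysed region.
    gene_tree, species_tree
        Rooted trees (newick strings/paths or :class:`RootedTree`).
    gene_to_species
        Mapping from gene-tree leaves to species-tree leaves.
    basal_reference
        Genes defining the ancestral intron sites (numbered 1..n).
    column_tolerance
        Alignment-jitter tolerance for merging same-phase sites; 0 requires
        exact column identity.
    method
        "dollo" (single gain per site; the default) or "fitch".
    cost_mode
        "serial-min" or "per-intron" splicing-time accounting.
    include_exceptions
        Whether genes flagged as lineage-specific exceptions join the
        canonical pathway computation.
    """

    def __init__(self,
                 structures: Union[Sequence[GeneStructure], str, Path],
                 alignment: Union[CodonAlignment, str, Path],
                 gene_tree: Union[RootedTree, str],
                 species_tree: Union[RootedTree, str],
                 gene_to_species: Mapping[str, str],
                 *,
                 basal_reference: Sequence[str] = (),
                 column_tolerance: int = 0,
                 method: str = "dollo",
                 cost_mode: str = cost.SERIAL_MIN,
                 cost_params: cost.CostParams = cost.CostParams(),
                 include_exceptions: bool = False):
        if method not in {"dollo", "fitch"}:
            raise ValueError(f"unknown reconstruction method {method!r}")
        if not isinstance(structures, (list, tuple)):
            structures = parse_structures(structures)
        self.structures = list(structures)
        if not isinstance(alignment, CodonAlignment):
            alignment = CodonAlignment.from_fasta(alignment)
        self.alignment = alignment
        self.gene_tree = gene_tree if isinstance(gene_tree, RootedTree) \
            else RootedTree.from_newick(gene_tree)
        self.species_tree = species_tree if isinstance(species_tree, RootedTree) \
            else RootedTree.from_newick(species_tree)
        self.gene_to_species = dict(gene_to_species)
        self.basal_reference = list(basal_reference)
        self.column_tolerance = column_tolerance
        self.method = method
        self.cost_mode = cost_mode
        self.cost_params = cost_params
        self.include_exceptions = include_exceptions

    @classmethod
    def from_fixture(cls, fixture, **options) -> "IntronEvolutionModel":
        """Build the model from a :class:`PaperFixture` or SimulationResult."""
        basal = options.pop("basal_reference", None)
        if basal is None:
            basal = getattr(fixture, "basal_reference", list(fixture.gene_to_species))
        return cls(fixture.structures, fixture.alignment, fixture.gene_tree,
                   fixture.species_tree, fixture.gene_to_species,
                   basal_reference=basal, **options)

    def fit(self) -> "IntronEvolutionResults":
        analysed = [g for g in self.structures
                    if g.gene_id in set(self.gene_tree.leaf_ids())]
        matrix = build_matrix(analysed, self.alignment,
                              basal_reference=self.basal_reference,
                              tolerance=self.column_tolerance,
                              include_exceptions=self.include_exceptions)
        rec = lca_map(self.gene_tree, self.species_tree, self.gene_to_species)
        reconstruct = dollo_reconstruct if self.method == "dollo" \
            else fitch_reconstruct
        states = reconstruct(matrix, self.species_tree, rec)
        history = infer_events(states, self.species_tree, matrix)
        pathway = summarize_pathway(history)
        counts = {g.gene_id: sum(1 for s in matrix.sites
                                 if matrix.state(g.gene_id, s.site_id) == "1")
                  for g in analysed if g.gene_id in matrix.genes}
        costs = cost.cost_table(counts, self.cost_params, self.cost_mode)
        return IntronEvolutionResults(
            model=self, matrix=matrix, reconciliation=rec, states=states,
            history=history, pathway=pathway, costs=costs)


@dataclass
class IntronEvolutionResults:
    """Fitted inference products with a printable summary."""

    model: IntronEvolutionModel
    matrix: IntronSiteMatrix
    reconciliation: Reconciliation
    states: AncestralStates
    history: EventHistory
    pathway: PathwaySummary
    costs: pd.DataFrame

    def lineage_of(self, gene_id: str) -> str:
        return self.reconciliation.gene_lineage[gene_id]

    def intron_position_table(self) -> pd.DataFrame:
        return intron_position_table(self.model.structures)

    def summary(self) -> str:
        rec = self.reconciliation
        lines = []
        add = lines.append
        add("Intron evolution inference")
        add("=" * 60)
        add(f"genes analysed:        {len(self.matrix.genes)}")
        add(f"intron sites:          {len(self.matrix.sites)} "
            f"({len(self.matrix.ancestral_sites())} ancestral)")
        add(f"reconstruction:        {self.states.method}")
        add(f"duplications:          {len(rec.duplication_nodes)} "
            f"(on: {', '.join(sorted(set(rec.mapping[n] for n in rec.duplication_nodes))) or '-'})")
        add(f"gene losses implied:   {rec.total_losses}")
        add(f"root intron count:     {len(self.history.root_complement)}")
        add(f"loss-bearing branches: {self.pathway.n_loss_branches}")
        add(f"site-level losses:     {self.pathway.total_site_losses}")
        add(f"intron gains:          {self.pathway.total_gains}")
        add("")
        add("Per-branch events (lineage, branch, sites):")
        for _, row in self.pathway.branch_table.iterrows():
            add(f"  {row['lineage']:<6} {row['branch_child']:<16} {row['sites']}")
        add("")
        add("Max cumulative losses per lineage:")
        for lid, n in sorted(self.pathway.max_cumulative_by_lineage.items()):
            add(f"  {lid:<6} {n}")
        add("")
        add("Expression time-cost extremes (minutes, "
            f"{self.model.cost_mode} mode):")
        if not self.costs.empty:
            lo = self.costs.loc[self.costs["n_introns"].idxmin()]
            hi = self.costs.loc[self.costs["n_introns"].idxmax()]
            for tag, row in (("fewest introns", lo), ("most introns", hi)):
                add(f"  {tag}: {row['gene_id']} ({int(row['n_introns'])} introns, "
                    f"{row['gene_length_kbp']:.3f} kbp, total >= "
                    f"{row['total_lower_bound']:.2f} min)")
        return "\n".join(lines)
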