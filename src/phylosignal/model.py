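"""Model/Results interface for the backbone signal-dissection analysis.

:class:`BackboneDissection` bundles the data of a study — a multi-locus
supermatrix, its partition scheme, monophyly constraints on the major clades,
and optionally a morphological matrix — and :meth:`BackboneDissection.fit`
runs the whole evaluation: enumerate every rooted backbone arrangement of
the constrained clades, expand each into a full candidate topology with a
frozen within-clade resolution, fit all candidates under a partitioned
substitution model, test them with RELL/KH/AU, decompose the signal between
the two best candidates into gene-wise dGLS, and (when morphology is given)
score each backbone's constrained parsimony tree length. The returned
:class:`BackboneDissectionResults` carries the estimates and a ``summary()``
table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np

from .alignment import (
    Alignment,
    OccupancyReport,
    PartitionScheme,
    occupancy_report,
    read_fasta,
    read_partition_file,
    trim_columns,
)
from .genesignal import (
    DeltaGLSRecord,
    SignalSummary,
    delta_gls_from_matrix,
    summarize_signal,
)
from .likelihood import SiteLnLMatrix, fit_candidates
from .parsimony import MorphMatrix, constrained_best_length, read_morph_tsv
from .topotest import (
    AUResult,
    ConfidenceSet,
    DEFAULT_N_REPS,
    DEFAULT_SCALES,
    au_test,
    confidence_set,
)
from .trees import (
    CladeConstraintSet,
    build_constrained_tree,
    enumerate_backbones,
    resolve_group,
    within_clade_resolution,
)


class BackboneDissection:
    """Constrained-backbone evaluation of a partitioned supermatrix.

    Parameters
    ----------
    alignment : Alignment
        The concatenated supermatrix.
    partition_scheme : PartitionScheme
        Locus -> column-range mapping.
    constraints : CladeConstraintSet
        Monophyletic clades whose arrangements are enumerated, plus outgroup.
    morphology : MorphMatrix, optional
        Discrete character matrix for per-backbone parsimony lengths.
    """

    def __init__(
        self,
        alignment: Alignment,
        partition_scheme: PartitionScheme,
        constraints: CladeConstraintSet,
        morphology: MorphMatrix | None = None,
        model_family: str = "GTR",
        gamma: bool = True,
        n_categories: int = 4,
        trim: bool = False,
        max_missing_fraction: float = 0.5,
    ):
        extra = constraints.all_taxa - set(alignment.taxa)
        if extra:
            raise ValueError(f"constraint taxa absent from alignment: {sorted(extra)}")
        self.constraints = constraints
        self.model_family = model_family
        self.gamma = gamma
        self.n_categories = n_categories
        self.occupancy: OccupancyReport = occupancy_report(alignment, partition_scheme)
        self.trimmed = trim
        if trim:
            alignment, kept, partition_scheme = trim_columns(
                alignment, partition_scheme, max_missing_fraction
            )
            self.kept_columns = kept
        else:
            self.kept_columns = np.arange(alignment.n_columns)
        self.alignment = alignment
        self.partition_scheme = partition_scheme
        self.morphology = morphology

    @classmethod
    def from_files(
        cls,
        supermatrix_fasta,
        partition_file,
        constraints_yaml,
        morphology_tsv=None,
        **kwargs,
    ) -> "BackboneDissection":
        aln = read_fasta(supermatrix_fasta)
        scheme = read_partition_file(partition_file)
        constraints = CladeConstraintSet.from_yaml(constraints_yaml)
        morph = read_morph_tsv(morphology_tsv) if morphology_tsv else None
        return cls(aln, scheme, constraints, morph, **kwargs)

    # ------------------------------------------------------------------
    def candidate_trees(self) -> tuple[dict[str, dendropy.Tree], dict[str, dendropy.Tree]]:
        """All backbone-constrained candidate topologies, plus the backbones.

        Within-clade subtrees are resolved once by neighbor joining and
        reused for every backbone, so candidates differ only in the deep
        arrangement of the constrained clades.
        """
        backbones = enumerate_backbones(self.constraints.clade_labels)
        subtrees = within_clade_resolution(self.alignment, self.constraints)
        og_tree = None
        if self.constraints.outgroup:
            og_tree = resolve_group(self.alignment, sorted(self.constraints.outgroup))
        width = len(str(len(backbones)))
        cands, bbs = {}, {}
        for i, bb in enumerate(backbones):
            tid = f"bb{i + 1:0{width}d}"
            bbs[tid] = bb
            cands[tid] = build_constrained_tree(bb, subtrees, og_tree)
        self._subtrees = subtrees
        self._outgroup_tree = og_tree
        return cands, bbs

    def fit(
        self,
        scales: Sequence[float] = DEFAULT_SCALES,
        n_reps: int = DEFAULT_N_REPS,
        alpha: float = 0.05,
        seed: int = 0,
        tol: float = 1e-4,
        dgls_threshold: float = 2.0,
        dgls_pair: tuple[str, str] | None = None,
        parsimony: bool | None = None,
        parsimony_seed: int | None = None,
    ) -> "BackboneDissectionResults":
        """Run the full dissection and return a results object."""
        candidates, backbones = self.candidate_trees()
        matrix = fit_candidates(
            self.alignment,
            self.partition_scheme,
            candidates,
            model_family=self.model_family,
            gamma=self.gamma,
            n_categories=self.n_categories,
            tol=tol,
        )
        au_results = au_test(matrix, scales=scales, n_reps=n_reps, seed=seed)
        cset = confidence_set(au_results, alpha=alpha)
        totals = matrix.total_lnl()
        order = [matrix.tree_ids[i] for i in np.argsort(totals)[::-1]]
        if dgls_pair is None:
            dgls_pair = (order[0], order[1]) if len(order) > 1 else None
        records: list[DeltaGLSRecord] = []
        summary: SignalSummary | None = None
        if dgls_pair is not None:
            records = delta_gls_from_matrix(
                matrix, dgls_pair[0], dgls_pair[1], threshold=dgls_threshold
            )
            summary = summarize_signal(records)
        if parsimony is None:
            parsimony = self.morphology is not None
        lengths: dict[str, int] = {}
        if parsimony and self.morphology is not None:
            pseed = seed if parsimony_seed is None else parsimony_seed
            for tid, bb in backbones.items():
                lengths[tid], _ = constrained_best_length(
                    self.morphology,
                    self.constraints,
                    bb,
                    self._subtrees,
                    self._outgroup_tree,
                    seed=pseed,
                )
        return BackboneDissectionResults(
            model=self,
            backbones=backbones,
            candidates=candidates,
            site_lnl=matrix,
            au_results=au_results,
            conf_set=cset,
            dgls_pair=dgls_pair,
            dgls_records=records,
            signal_summary=summary,
            parsimony_lengths=lengths,
            seed=seed,
        )


@dataclass
class BackboneDissectionResults:
    """Fitted quantities of a backbone dissection, with a summary table."""

    model: BackboneDissection
    backbones: dict[str, dendropy.Tree]
    candidates: dict[str, dendropy.Tree]
    site_lnl: SiteLnLMatrix
    au_results: list[AUResult]
    conf_set: ConfidenceSet
    dgls_pair: tuple[str, str] | None
    dgls_records: list[DeltaGLSRecord] = field(default_factory=list)
    signal_summary: SignalSummary | None = None
    parsimony_lengths: dict[str, int] = field(default_factory=dict)
    seed: int = 0

    @property
    def ml_tree_id(self) -> str:
        return self.conf_set.ml_tree_id

    def au_frame(self):
        """AU/KH results as a pandas DataFrame, best tree first."""
        import pandas as pd

        rows = [
            {
                "tree_id": r.tree_id,
                "lnL": r.total_lnl,
                "p_KH": r.p_kh,
                "p_AU": r.p_au,
                "in_confidence_set": r.tree_id in self.conf_set,
            }
            for r in sorted(self.au_results, key=lambda x: -x.total_lnl)
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        occ = self.model.occupancy.per_locus
        m = self.model
        lines = [
            "Backbone signal dissection",
            "=" * 60,
            f"supermatrix: {m.alignment.n_taxa} taxa x {m.alignment.n_columns} sites, "
            f"{len(m.partition_scheme)} loci",
            f"model: {m.model_family}"
            + (f"+G{m.n_categories}" if m.gamma else "")
            + f"; candidates: {len(self.candidates)} backbones",
            f"per-locus occupancy: "
            f"{min(occ.values()):.2f}-{max(occ.values()):.2f}",
            "",
            "tree_id      lnL          p_KH     p_AU   member",
        ]
        for r in sorted(self.au_results, key=lambda x: -x.total_lnl):
            star = "*" if r.tree_id == self.ml_tree_id else " "
            member = "yes" if r.tree_id in self.conf_set else "no"
            lines.append(
                f"{r.tree_id}{star}  {r.total_lnl:>13.3f}  {r.p_kh:>7.4f}  "
                f"{r.p_au:>7.4f}  {member}"
            )
        lines.append(
            f"confidence set at alpha={self.conf_set.alpha}: "
            f"{len(self.conf_set.members)} of {len(self.candidates)} trees"
        )
        if self.signal_summary is not None:
            s = self.signal_summary
            lines += [
                "",
                f"dGLS {self.dgls_pair[0]} vs {self.dgls_pair[1]}: "
                f"{s.n_favor_t1} favor first, {s.n_favor_t2} favor second, "
                f"{s.n_uninformative} uninformative (of {s.n_genes} loci)",
            ]
        if self.parsimony_lengths:
            lines += ["", "constrained parsimony lengths (morphology):"]
            for tid, L in sorted(self.parsimony_lengths.items()):
                lines.append(f"  {tid}: {L}")
        return "\n".join(lines)
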