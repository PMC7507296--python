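"""Rank-level abundance profiles and Bray-Curtis drift between model versions.

Per-read species predictions are traced up the taxonomy to a chosen rank and
tallied into a relative-abundance profile. Two presentation/analysis helpers
follow the convention used when tracking how a classifier's picture of a
fixed sample changes as its training database grows:

* ``bin_others`` pools taxa below a relative-abundance threshold (default
  5%) into two synthetic bins, "Others: New" for taxa first seen in the most
  recent training division and "Others: Old" for the rest;
* ``bray_curtis`` measures the dissimilarity between two profiles of the
  same sample under consecutive model versions, over *all* taxon labels
  (never the binned presentation), as BC = sum|p-q| / sum(p+q).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .classify import Prediction
from .taxonomy import TaxonomyTree

__all__ = [
    "OTHERS_OLD",
    "OTHERS_NEW",
    "AbundanceProfile",
    "profile_from_predictions",
    "bin_others",
    "bray_curtis",
    "write_profile_tsv",
    "plot_profiles",
]

OTHERS_OLD = "Others: Old"
OTHERS_NEW = "Others: New"

TaxonKey = Union[int, str]  # taxid, or one of the two synthetic bin labels


@dataclass
class AbundanceProfile:
    """Relative abundances at one rank; fractions sum to 1 with unresolved."""

    rank: str
    abundances: dict[TaxonKey, float]
    n_reads: int
    unresolved_fraction: float = 0.0

    def mass(self) -> float:
        return sum(self.abundances.values()) + self.unresolved_fraction


def profile_from_predictions(
    predictions: Sequence[Prediction], tree: TaxonomyTree, rank: str
) -> AbundanceProfile:
    """Tally predictions into a relative-abundance profile at one rank.

    Each predicted species is traced to its ancestor at ``rank``;
    predictions whose lineage has no node at that rank pool into
    ``unresolved_fraction``.
    """
    if not predictions:
        raise ValueError("cannot profile an empty prediction set")
    tally: Counter[int] = Counter()
    unresolved = 0
    for pred in predictions:
        ancestor = tree.ancestor_at_rank(pred.predicted_species, rank)
        if ancestor is None:
            unresolved += 1
        else:
            tally[ancestor] += 1
    n = len(predictions)
    return AbundanceProfile(
        rank=rank,
        abundances={taxid: count / n for taxid, count in sorted(tally.items())},
        n_reads=n,
        unresolved_fraction=unresolved / n,
    )


def bin_others(
    profile: AbundanceProfile,
    threshold: float = 0.05,
    new_taxa: Iterable[int] = (),
) -> AbundanceProfile:
    """Pool low-abundance taxa into "Others: Old" / "Others: New" bins.

    Taxa strictly below ``threshold`` move to "Others: New" if their taxid
    is in ``new_taxa`` (taxa first present in the most recent training
    division), otherwise "Others: Old". Taxa at or above the threshold are
    kept verbatim; total mass is conserved exactly.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    new_taxa = set(new_taxa)
    kept: dict[TaxonKey, float] = {}
    others_old = 0.0
    others_new = 0.0
    for taxon, abundance in profile.abundances.items():
        if isinstance(taxon, str):
            raise ValueError("profile already contains synthetic bins")
        if abundance < threshold:
            if taxon in new_taxa:
                others_new += abundance
            else:
                others_old += abundance
        else:
            kept[taxon] = abundance
    if others_old > 0.0:
        kept[OTHERS_OLD] = others_old
    if others_new > 0.0:
        kept[OTHERS_NEW] = others_new
    return AbundanceProfile(
        rank=profile.rank,
        abundances=kept,
        n_reads=profile.n_reads,
        unresolved_fraction=profile.unresolved_fraction,
    )


def bray_curtis(p: AbundanceProfile, q: AbundanceProfile) -> float:
    """Bray-Curtis dissimilarity between two profiles at the same rank.

    BC(p, q) = sum_t |p_t - q_t| / sum_t (p_t + q_t) over the union of
    taxon labels, absent taxa counting 0. For unit-sum profiles this is
    half the L1 distance; 0 means identical composition, 1 disjoint.
    The unresolved fraction is excluded: the comparison runs over taxon
    labels only.
    """
    if p.rank != q.rank:
        raise ValueError(f"rank mismatch: {p.rank!r} vs {q.rank!r}")
    taxa = set(p.abundances) | set(q.abundances)
    num = sum(abs(p.abundances.get(t, 0.0) - q.abundances.get(t, 0.0)) for t in taxa)
    den = sum(p.abundances.get(t, 0.0) + q.abundances.get(t, 0.0) for t in taxa)
    if den == 0.0:
        return 0.0
    return num / den


def write_profile_tsv(
    path: str | Path, profile: AbundanceProfile, tree: Optional[TaxonomyTree] = None
) -> None:
    """Write a profile as TSV: rank, taxid, name, abundance.

    Synthetic bins use their label in both the taxid and name columns;
    names require a tree and fall back to the taxid otherwise.
    """
    with open(path, "w") as fh:
        fh.write("rank\ttaxid\tname\tabundance\n")
        for taxon, abundance in profile.abundances.items():
            if isinstance(taxon, str):
                name = taxon
            elif tree is not None:
                name = tree.name(taxon)
            else:
                name = str(taxon)
            fh.write(f"{profile.rank}\t{taxon}\t{name}\t{abundance:.6f}\n")
        if profile.unresolved_fraction > 0.0:
            fh.write(
                f"{profile.rank}\tunresolved\tunresolved\t"
                f"{profile.unresolved_fraction:.6f}\n"
            )


def plot_profiles(
    profiles: dict[str, AbundanceProfile],
    tree: Optional[TaxonomyTree] = None,
    ax=None,
):
    """Stacked-bar plot of profiles keyed by model-version label.

    Convenience visualisation of how the predicted composition of one
    sample shifts across model versions; requires matplotlib.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.5 * len(profiles) + 2, 4))
    labels = list(profiles)
    taxa: list[TaxonKey] = []
    for prof in profiles.values():
        for taxon in prof.abundances:
            if taxon not in taxa:
                taxa.append(taxon)
    bottom = [0.0] * len(labels)
    for taxon in taxa:
        heights = [profiles[lab].abundances.get(taxon, 0.0) for lab in labels]
        if isinstance(taxon, str):
            name = taxon
        elif tree is not None:
            name = tree.name(taxon)
        else:
            name = str(taxon)
        ax.bar(labels, heights, bottom=bottom, label=name)
        bottom = [b + h for b, h in zip(bottom, heights)]
    ax.set_ylabel("relative abundance")
    ax.legend(fontsize="small", bbox_to_anchor=(1.02, 1), loc="upper left")
    return ax
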