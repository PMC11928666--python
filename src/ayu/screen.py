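"""Secretome-screening rules for metagenome-scale application.

Transmembrane proteins confound exported-protein prediction, so they are
filtered first: a protein counts as membrane when at least 5% of its length
lies in transmembrane helices or beta barrels.  A lone N-terminal helix is
suspect — signal peptides are routinely miscalled as transmembrane helices —
so that case is accepted as membrane only when a membrane GO annotation
corroborates it.

The summary then tallies, per predicted location, how many proteins carry a
signal peptide (exported proteins without one indicate signal-peptide-
independent secretion systems), checks signal-peptide consistency within
sequence clusters (co-clustered proteins should share secretion signals),
and computes per-gene metatranscriptome/metagenome log2 abundance ratios.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .seq_io import AnnotationBundle

MEMBRANE_TM_FRACTION = 0.05
N_TERMINAL_SPAN = 30        # a helix starting within the first 30 residues
SP_POSITIVE_THRESHOLD = 0.5
RPKG_EPS = 1e-3


def classify_membrane(bundle: AnnotationBundle, length: int) -> bool:
    """Membrane-protein rule: TM-residue fraction >= 5% of protein length,
    except that a single N-terminal helix (start <= 30) with no other TM
    evidence needs a membrane GO term to count."""
    helices = [(s, e) for s, e, k in bundle.tm_segments if k == "helix"]
    barrels = [(s, e) for s, e, k in bundle.tm_segments if k == "barrel"]
    for s, e in helices + barrels:
        if not (1 <= s <= e <= length):
            raise ValueError(f"TM segment {s}-{e} outside 1..{length}")
    tm_residues = sum(e - s + 1 for s, e in helices + barrels)
    if tm_residues / length < MEMBRANE_TM_FRACTION:
        return False
    if len(helices) == 1 and not barrels and helices[0][0] <= N_TERMINAL_SPAN:
        return bool(bundle.go_membrane)
    return True


def sp_positive(bundle: AnnotationBundle) -> bool:
    return bundle.sp_probs[0] >= SP_POSITIVE_THRESHOLD


def secretome_summary(predictions: pd.DataFrame,
                      bundles: dict[str, AnnotationBundle],
                      lengths: dict[str, int],
                      clusters=None,
                      abundances: pd.DataFrame | None = None) -> dict:
    """Screening summary tables.

    predictions: the prediction TSV frame (id, p_*, call, has_sp).
    clusters: output of greedy_cluster at 70% identity / 95% coverage.
    abundances: optional frame with columns id, rpkg_metaG, rpkg_metaT and
        grouping tags (depth, and optionally taxon/function).

    Returns a dict with:
      * class_sp_fraction — per predicted class, fraction of proteins whose
        any-signal-peptide probability reaches 0.5;
      * partition_fractions — membrane / cytoplasmic / periplasmic /
        extracellular / unclassified fractions (membrane overrides the
        model call); sums to 1;
      * cluster_sp_consistency — per cluster with >= 1 signal-peptide-
        positive member: positive count vs cluster size;
      * expression — per gene log2((metaT + eps)/(metaG + eps)) with its
        grouping tags, eps = 1e-3.
    """
    ids = list(predictions["id"])
    missing = [i for i in ids if i not in bundles or i not in lengths]
    if missing:
        raise ValueError(f"ids without annotation/length: {missing[:5]}")

    membrane = {i: classify_membrane(bundles[i], lengths[i]) for i in ids}
    calls = dict(zip(predictions["id"], predictions["call"]))

    class_sp: dict[str, tuple[int, int]] = {}
    for pid in ids:
        call = calls[pid]
        n, s = class_sp.get(call, (0, 0))
        class_sp[call] = (n + 1, s + int(sp_positive(bundles[pid])))
    class_sp_fraction = {c: s / n for c, (n, s) in class_sp.items()}

    partition_counts = {"membrane": 0, "cytoplasmic": 0, "periplasmic": 0,
                        "extracellular": 0, "unclassified": 0}
    for pid in ids:
        key = "membrane" if membrane[pid] else calls[pid]
        partition_counts[key] += 1
    total = len(ids)
    partition_fractions = {k: v / total for k, v in partition_counts.items()}

    consistency_rows = []
    if clusters is not None:
        for cluster in clusters:
            pos = sum(int(sp_positive(bundles[m])) for m in cluster.members
                      if m in bundles)
            if pos >= 1:
                consistency_rows.append({
                    "representative": cluster.representative,
                    "sp_positive": pos, "size": len(cluster.members)})
    consistency = pd.DataFrame(
        consistency_rows, columns=["representative", "sp_positive", "size"])

    expression = None
    if abundances is not None:
        bad = set(abundances["id"]) - set(ids)
        if bad:
            raise ValueError(f"abundance ids absent from predictions: "
                             f"{sorted(bad)[:5]}")
        if (abundances[["rpkg_metaG", "rpkg_metaT"]] < 0).any().any():
            raise ValueError("negative abundance values")
        expression = abundances.copy()
        expression["log2_t_over_g"] = np.log2(
            (expression["rpkg_metaT"] + RPKG_EPS) /
            (expression["rpkg_metaG"] + RPKG_EPS))
        expression["call"] = expression["id"].map(calls)
        expression["membrane"] = expression["id"].map(membrane)

    return {
        "class_sp_fraction": class_sp_fraction,
        "partition_fractions": partition_fractions,
        "cluster_sp_consistency": consistency,
        "expression": expression,
    }
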