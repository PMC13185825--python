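"""Classification of SVs against repeat and gene annotation, and composition matrices.

A repeat SV ("rep-SV") is an SV whose effective interval overlaps at least
one annotated repeat by >= 1 bp and whose length is < 100 kbp.  Each rep-SV
is assigned the single REP type with the largest summed overlap (ties go to
the lexicographically smaller label).  Evolutionary state is a function of
the cohort genotype pattern alone:

* shared           — >= 1 taurine and >= 1 indicine carrier
* private_taurine  — >= 2 taurine carriers, no indicine carrier
* private_indicine — >= 2 indicine carriers, no taurine carrier
* specific (young) — exactly one carrier in the whole cohort
* unassigned       — anything else

Hybrid individuals never decide shared/private; they only count toward the
total-carrier test for "specific".
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import pyranges as pr

from .sv_io import MISSING, GeneTrack, RepeatTrack, SVCallSet, SVRecord

logger = logging.getLogger(__name__)

REP_SV_MAX_LEN = 100_000

SIZE_CLASSES = (("small", 50, 200), ("medium", 200, 500), ("large", 500, np.inf))


def effective_interval(sv: SVRecord) -> tuple[int, int]:
    """Half-open 0-based interval affected by an SV.

    DEL/DUP/INV span [pos-1, end); an INS is treated as occupying
    [pos-1, pos-1+svlen) — its start plus the insertion length.
    A zero-length INS yields an empty interval.
    """
    if sv.svtype == "INS":
        if sv.svlen is None:
            raise ValueError(f"{sv.id}: INS without svlen")
        if sv.svlen == 0:
            warnings.warn(f"{sv.id}: zero-length INS -> empty interval")
        return sv.pos - 1, sv.pos - 1 + sv.svlen
    return sv.pos - 1, sv.end


def classify_rep_sv(sv: SVRecord, repeats: RepeatTrack):
    """(is_rep, rep_type, overlap_bp, all_overlaps) for a single SV."""
    s, e = effective_interval(sv)
    overlaps: dict[str, int] = {}
    for f in repeats.features:
        if f.chrom != sv.chrom:
            continue
        ov = min(e, f.end) - max(s, f.start)
        if ov > 0:
            overlaps[f.rep_type] = overlaps.get(f.rep_type, 0) + int(ov)
    total = sum(overlaps.values())
    is_rep = total >= 1 and sv.svlen < REP_SV_MAX_LEN
    if not is_rep:
        return False, None, 0, overlaps
    rep_type = min(overlaps, key=lambda t: (-overlaps[t], t))
    return True, rep_type, overlaps[rep_type], overlaps


def assign_state(presence: np.ndarray, subspecies) -> str:
    """Evolutionary state from a per-individual presence vector (-1 missing)."""
    sub = np.asarray(subspecies)
    pres = np.asarray(presence)
    carriers = pres == 1
    t = int(np.sum(carriers & (sub == "taurine")))
    i = int(np.sum(carriers & (sub == "indicine")))
    tot = int(np.sum(carriers))
    if tot == 0:
        raise ValueError("zero carriers: record should have been filtered upstream")
    if tot == 1:
        return "specific"
    if t >= 1 and i >= 1:
        return "shared"
    if t >= 2 and i == 0:
        return "private_taurine"
    if i >= 2 and t == 0:
        return "private_indicine"
    return "unassigned"


def annotate_context(sv: SVRecord, genes: GeneTrack) -> str:
    """exon > intron > intergenic, by effective-interval overlap priority."""
    s, e = effective_interval(sv)
    in_gene = False
    for f in genes.features:
        if f.chrom != sv.chrom or min(e, f.end) <= max(s, f.start):
            continue
        if f.kind == "exon":
            return "exon"
        in_gene = True
    return "intron" if in_gene else "intergenic"


# ---------------------------------------------------------------------------
# bulk annotation
# ---------------------------------------------------------------------------

def _effective_df(callset: SVCallSet) -> pd.DataFrame:
    rows = []
    for idx, r in enumerate(callset.records):
        s, e = effective_interval(r)
        rows.append((r.chrom, s, e, idx))
    return pd.DataFrame(rows, columns=["Chromosome", "Start", "End", "sv_idx"])


def annotate_cohort(
    callset: SVCallSet,
    repeats: RepeatTrack,
    genes: GeneTrack | None = None,
    metadata: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Annotate every SV in a call set; one row per SV.

    Columns: sv_id, chrom, pos, end, svtype, svlen, is_rep, rep_type,
    overlap_bp, state, is_young, context.  ``state`` needs ``metadata``
    (individual/subspecies); ``context`` needs ``genes``.
    """
    svdf = _effective_df(callset)
    n = len(callset.records)

    # repeat overlaps via a bulk interval join
    dom_type = np.full(n, "", dtype=object)
    dom_bp = np.zeros(n, dtype=int)
    total_bp = np.zeros(n, dtype=int)
    if len(repeats) and n:
        j = pr.PyRanges(svdf).join(repeats.to_pyranges()).df
        if len(j):
            ov = np.minimum(j["End"], j["End_b"]) - np.maximum(j["Start"], j["Start_b"])
            j = j.assign(ov=ov)
            j = j[j["ov"] > 0]
            per = j.groupby(["sv_idx", "rep_type"])["ov"].sum().reset_index()
            tot = per.groupby("sv_idx")["ov"].sum()
            total_bp[tot.index.to_numpy()] = tot.to_numpy()
            per = per.sort_values(["sv_idx", "ov", "rep_type"],
                                  ascending=[True, False, True])
            dom = per.drop_duplicates("sv_idx", keep="first")
            dom_type[dom["sv_idx"].to_numpy()] = dom["rep_type"].to_numpy()
            dom_bp[dom["sv_idx"].to_numpy()] = dom["ov"].to_numpy()

    svlens = np.array([r.svlen for r in callset.records])
    is_rep = (total_bp >= 1) & (svlens < REP_SV_MAX_LEN)
    dom_type[~is_rep] = ""
    dom_bp[~is_rep] = 0

    # genomic context
    context = np.full(n, "intergenic", dtype=object)
    if genes is not None and len(genes) and n:
        gdf = genes.df
        j = pr.PyRanges(svdf).join(
            pr.PyRanges(gdf[["Chromosome", "Start", "End", "kind"]].copy())
        ).df
        if len(j):
            ov = np.minimum(j["End"], j["End_b"]) - np.maximum(j["Start"], j["Start_b"])
            j = j[ov > 0]
            gene_hit = j.loc[j["kind"] == "gene", "sv_idx"].unique()
            exon_hit = j.loc[j["kind"] == "exon", "sv_idx"].unique()
            context[gene_hit] = "intron"
            context[exon_hit] = "exon"

    # evolutionary state
    state = np.full(n, "unassigned", dtype=object)
    if metadata is not None and callset.samples:
        sub = (
            metadata.set_index("individual")
            .loc[callset.samples, "subspecies"]
            .to_numpy()
        )
        for idx, r in enumerate(callset.records):
            state[idx] = assign_state(r.presence(), sub)

    return pd.DataFrame(
        {
            "sv_id": [r.id for r in callset.records],
            "chrom": [r.chrom for r in callset.records],
            "pos": [r.pos for r in callset.records],
            "end": [r.end for r in callset.records],
            "svtype": [r.svtype for r in callset.records],
            "svlen": svlens,
            "is_rep": is_rep,
            "rep_type": dom_type,
            "overlap_bp": dom_bp,
            "state": state,
            "is_young": state == "specific",
            "context": context,
        }
    )


def composition_matrix(
    annotations: pd.DataFrame,
    callset: SVCallSet,
    metadata: pd.DataFrame,
    state_filter: str = "all",
    count_mode: str = "dominant",
) -> pd.DataFrame:
    """Individuals x REP-type counts of carried rep-SVs.

    ``state_filter`` selects one evolutionary state ("all", "shared",
    "private" [either subspecies], "specific"); a carrier is any individual
    with a present genotype.  ``count_mode`` is fixed to "dominant": each SV
    contributes once, to its dominant REP type.
    """
    if count_mode != "dominant":
        raise NotImplementedError("only dominant-type counting is implemented")
    ann = annotations
    sel = ann["is_rep"].to_numpy()
    if state_filter != "all":
        if state_filter == "private":
            sel = sel & ann["state"].str.startswith("private_").to_numpy()
        else:
            sel = sel & (ann["state"] == state_filter).to_numpy()
    idx = np.flatnonzero(sel)
    types = sorted(set(ann.loc[sel, "rep_type"]) - {""})
    out = pd.DataFrame(
        0, index=list(metadata["individual"]), columns=types, dtype=int
    )
    if not len(idx):
        warnings.warn(f"empty selection for state_filter={state_filter!r}")
        return out
    pres = callset.presence_matrix()[idx] == 1
    tcol = ann["rep_type"].to_numpy()[idx]
    for t in types:
        out[t] = pres[tcol == t].sum(axis=0)
    return out


def summarize_size_classes(svlens) -> pd.Series:
    """Proportions of small [50,200), medium [200,500), large [500,inf) SVs."""
    v = np.asarray(svlens)
    if np.any(v < 50):
        raise ValueError("SV lengths < 50 bp present; upstream filter violated")
    total = len(v)
    out = {}
    for name, lo, hi in SIZE_CLASSES:
        out[name] = float(np.sum((v >= lo) & (v < hi))) / total
    return pd.Series(out)
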