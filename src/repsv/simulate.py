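"""Synthetic two-subspecies SV cohorts with known ground truth.

The generator emits the statistical structure the downstream analyses assume
— not sequence-level realism.  Per SV it draws an evolutionary state
(shared / private to one subspecies / individual-specific), a repeat status
and mediating REP type, a length from a background law plus discrete peak
components, a genomic placement (optionally X-biased for large repeat SVs)
and a cohort genotype pattern that realises the state.  A repeat track is
co-generated so that classification truth is guaranteed: every repeat SV
receives a co-placed repeat interval of its REP type and every non-repeat SV
is kept clear of all repeat intervals.

Determinism: a fixed config seed yields byte-identical outputs.  All
randomness flows through one ``numpy`` Generator; no dict-ordering or
float-reduction ambiguity enters the draw sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sv_io import (
    MISSING,
    GeneFeature,
    GeneTrack,
    RepeatFeature,
    RepeatTrack,
    SVCallSet,
    SVRecord,
)
from . import model_select

STATES = ("shared", "private_taurine", "private_indicine", "specific")


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeModel:
    chromosomes: tuple  # ((name, length), ...)
    x_name: str = "X"

    def __post_init__(self):
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        if any(l <= 0 for _, l in self.chromosomes):
            raise ValueError("chromosome lengths must be > 0")
        if names.count(self.x_name) != 1:
            raise ValueError(f"genome must contain exactly one X ({self.x_name})")
        if len(names) - 1 < 2:
            raise ValueError("need at least 2 autosomes")

    @property
    def names(self):
        return [c for c, _ in self.chromosomes]

    @property
    def lengths(self):
        return dict(self.chromosomes)

    def autosomes(self):
        return [(c, l) for c, l in self.chromosomes if c != self.x_name]


def default_genome() -> GenomeModel:
    """Desk-scale stand-in for a cattle-like karyotype: 29 autosomes of 1 Mb + X of 1.5 Mb."""
    chroms = tuple((str(i), 1_000_000) for i in range(1, 30)) + (("X", 1_500_000),)
    return GenomeModel(chroms)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakComponent:
    """One discrete length-peak: uniform on [lo, hi], mediated by one REP type."""
    center: float
    lo: float
    hi: float
    weight: float
    rep_type: str


#: the four modal length peaks of the repeat SV spectrum with their windows
DEFAULT_PEAKS = (
    PeakComponent(140, 125, 158, 0.18, "Bov-A2"),
    PeakComponent(280, 252, 316, 0.12, "Bov-A2"),
    PeakComponent(1150, 1018, 1263, 0.09, "LTR/ERVK"),
    PeakComponent(8400, 7686, 9689, 0.06, "LTR/ERVK"),
)

DEFAULT_REP_TYPES = {
    "Bov-A2": 0.25,
    "Bov-tA": 0.15,
    "BovB": 0.08,
    "LINE/L1": 0.20,
    "LTR/ERVK": 0.10,
    "Satellite": 0.07,
    "Simple_repeat": 0.10,
    "LINE/Dong-R4": 0.05,
}

#: size threshold above which X-placement bias applies (the sharp-increase split)
LARGE_SV_THRESHOLD = 8000


@dataclass(frozen=True)
class CohortConfig:
    n_taurine: int = 12
    n_indicine: int = 12
    n_hybrid: int = 6
    n_svs: int = 5000
    rep_fraction: float = 0.74  # roughly three-quarters of SVs are repeat-mediated
    rep_types: tuple = tuple(DEFAULT_REP_TYPES.items())
    state_proportions: tuple = (
        ("shared", 0.45),
        ("private_taurine", 0.15),
        ("private_indicine", 0.15),
        ("specific", 0.25),
    )
    background_weight: float = 0.55
    peaks: tuple = DEFAULT_PEAKS
    rep_size_range: tuple = (50, 20_000)     # log-uniform background for repeat SVs
    nonrep_size_range: tuple = (50, 5_000)   # kept small so repeat-free placement is feasible
    x_bias: float = 1.0
    x_bias_threshold: int = LARGE_SV_THRESHOLD
    missing_rate: float = 0.02
    placement_margin: int = 150  # bp kept free around every SV interval
    decoy_repeats_per_mb: float = 30.0
    genes_per_mb: float = 3.0
    exons_per_gene: int = 3
    svtype_weights: tuple = (("INS", 0.45), ("DEL", 0.45), ("DUP", 0.05), ("INV", 0.05))
    seed: int = 0

    def __post_init__(self):
        probs = dict(self.state_proportions)
        if any(p < 0 or p > 1 for p in probs.values()) or not np.isclose(sum(probs.values()), 1.0):
            raise ValueError("state_proportions must lie in [0,1] and sum to 1")
        tw = dict(self.rep_types)
        if not np.isclose(sum(tw.values()), 1.0):
            raise ValueError("rep_types weights must sum to 1")
        peak_w = sum(p.weight for p in self.peaks)
        if not np.isclose(self.background_weight + peak_w, 1.0):
            raise ValueError("background_weight + peak weights must sum to 1")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate in [0, 1)")
        if self.x_bias <= 0:
            raise ValueError("x_bias must be > 0")
        if probs.get("private_taurine", 0) > 0 and self.n_taurine < 2:
            raise ValueError("private_taurine weight > 0 requires n_taurine >= 2")
        if probs.get("private_indicine", 0) > 0 and self.n_indicine < 2:
            raise ValueError("private_indicine weight > 0 requires n_indicine >= 2")


@dataclass
class CohortSim:
    """Everything :func:`simulate_cohort` produces."""
    cohort: SVCallSet          # all SVs x all individuals, full genotype matrix
    callsets: list             # one per-individual discovery call set (present SVs only)
    repeats: RepeatTrack
    genes: GeneTrack
    metadata: pd.DataFrame     # individual, subspecies, breed, sex
    truth: pd.DataFrame        # per-SV ground truth
    genome: GenomeModel
    config: CohortConfig


# ---------------------------------------------------------------------------
# genotype patterns
# ---------------------------------------------------------------------------

def _draw_pattern(rng, state, sub, missing_rate):
    """Draw per-individual presence (with missingness) realising ``state``.

    Subspecies allele frequencies are Beta draws conditioned on the state;
    presence is Bernoulli per individual; hybrids get the mean of the two
    subspecies frequencies.  The draw is rejected until the pattern, as
    recomputed from non-missing calls, still satisfies the state definition.
    """
    is_t = sub == "taurine"
    is_i = sub == "indicine"
    is_h = sub == "hybrid"
    n = len(sub)
    for _ in range(1000):
        if state == "specific":
            pres = np.zeros(n, dtype=np.int8)
            pres[rng.integers(n)] = 1
        else:
            if state == "shared":
                ft, fi = rng.beta(1.5, 1.5), rng.beta(1.5, 1.5)
            elif state == "private_taurine":
                ft, fi = rng.beta(2.0, 2.0), 0.0
            else:  # private_indicine
                ft, fi = 0.0, rng.beta(2.0, 2.0)
            freq = np.where(is_t, ft, np.where(is_i, fi, 0.5 * (ft + fi)))
            if state != "shared":
                freq[is_h] = 0.0  # keep private patterns unambiguous
            pres = (rng.random(n) < freq).astype(np.int8)
        miss = rng.random(n) < missing_rate
        eff = np.where(miss, MISSING, pres)
        t = int(np.sum((eff == 1) & is_t))
        i = int(np.sum((eff == 1) & is_i))
        tot = int(np.sum(eff == 1))
        ok = (
            (state == "specific" and tot == 1)
            or (state == "shared" and t >= 1 and i >= 1)
            or (state == "private_taurine" and t >= 2 and i == 0 and tot == t)
            or (state == "private_indicine" and i >= 2 and t == 0 and tot == i)
        )
        if ok:
            if state in ("shared",):
                hetp = freq
            else:
                hetp = np.full(n, 0.5)
            gt = np.where(eff == 1, np.where(rng.random(n) < hetp, 2, 1), eff)
            return gt.astype(np.int8)
    raise RuntimeError(f"could not realise state {state}")  # pragma: no cover


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _sizes(rng, n, config, is_rep):
    """Lengths: repeat SVs from background + peaks, non-repeat from background only."""
    out = np.empty(n)
    lo, hi = config.nonrep_size_range
    rlo, rhi = config.rep_size_range
    comp_w = np.array([config.background_weight] + [p.weight for p in config.peaks])
    comp_w = comp_w / comp_w.sum()
    which = rng.choice(len(comp_w), size=n, p=comp_w)
    peak_idx = np.full(n, -1)
    for j in range(n):
        if not is_rep[j]:
            out[j] = np.exp(rng.uniform(np.log(lo), np.log(hi)))
        elif which[j] == 0:
            out[j] = np.exp(rng.uniform(np.log(rlo), np.log(rhi)))
        else:
            p = config.peaks[which[j] - 1]
            out[j] = rng.uniform(p.lo, p.hi)
            peak_idx[j] = which[j] - 1
    return np.maximum(out.astype(int), 50), peak_idx


def simulate_cohort(config: CohortConfig, genome: GenomeModel | None = None) -> CohortSim:
    """Generate a cohort of SV call sets with repeat/gene tracks and truth labels."""
    if genome is None:
        genome = default_genome()
    rng = np.random.default_rng(config.seed)

    # --- individuals -------------------------------------------------------
    ind, sub, breed = [], [], []
    for pre, n, lab in [
        ("TAU", config.n_taurine, "taurine"),
        ("IND", config.n_indicine, "indicine"),
        ("HYB", config.n_hybrid, "hybrid"),
    ]:
        for i in range(n):
            ind.append(f"{pre}{i + 1:03d}")
            sub.append(lab)
            breed.append(f"{pre}_breed{i % 3 + 1}")
    sub = np.array(sub)
    metadata = pd.DataFrame(
        {
            "individual": ind,
            "subspecies": sub,
            "breed": breed,
            "sex": rng.choice(["F", "M"], size=len(ind)),
        }
    )

    # --- per-SV draws ------------------------------------------------------
    n = config.n_svs
    state_names, state_p = zip(*config.state_proportions)
    states = np.array(state_names)[rng.choice(len(state_names), size=n, p=np.array(state_p))]
    is_rep = rng.random(n) < config.rep_fraction
    svlen, peak_idx = _sizes(rng, n, config, is_rep)
    type_names, type_w = zip(*config.rep_types)
    type_w = np.array(type_w) / np.sum(type_w)
    rep_type = np.array([
        (config.peaks[peak_idx[j]].rep_type if peak_idx[j] >= 0
         else type_names[rng.choice(len(type_names), p=type_w)])
        if is_rep[j] else ""
        for j in range(n)
    ], dtype=object)
    svt_names, svt_w = zip(*config.svtype_weights)
    svtypes = np.array(svt_names)[rng.choice(len(svt_names), size=n, p=np.array(svt_w))]

    # placement: probability ~ chromosome length, X multiplied by x_bias for
    # large repeat SVs.  Effective intervals are kept pairwise disjoint with
    # a free margin so that co-placed repeats never straddle foreign SVs and
    # the dominant-REP-type truth labels are exact.
    names = genome.names
    lens = np.array([l for _, l in genome.chromosomes], dtype=float)
    xi = names.index(genome.x_name)
    base_w = lens / lens.sum()
    biased_w = base_w.copy()
    biased_w[xi] *= config.x_bias
    biased_w /= biased_w.sum()
    chrom_idx = np.empty(n, dtype=int)
    pos = np.empty(n, dtype=int)
    margin = config.placement_margin
    booked: dict[int, list] = {c: [] for c in range(len(names))}  # sorted (start,end)

    import bisect

    def _book(c, s0, e0):
        iv = booked[c]
        i = bisect.bisect_left(iv, (s0, e0))
        if i > 0 and iv[i - 1][1] + margin > s0:
            return False
        if i < len(iv) and iv[i][0] - margin < e0:
            return False
        iv.insert(i, (s0, e0))
        return True

    place_order = sorted(range(n), key=lambda j: (-svlen[j], j))  # big first
    for j in place_order:
        w = biased_w if (is_rep[j] and svlen[j] > config.x_bias_threshold) else base_w
        span = int(svlen[j])  # insertions use the effective span too, to stay in bounds
        for attempt in range(500):
            c = rng.choice(len(names), p=w)
            hi = int(lens[c]) - span - 1
            if hi < 1:
                continue
            p1 = int(rng.integers(1, hi + 1))  # 1-based start
            if _book(c, p1 - 1, p1 - 1 + span):
                chrom_idx[j] = c
                pos[j] = p1
                break
        else:  # pragma: no cover
            raise RuntimeError(
                "could not place SVs without overlap; enlarge the genome or "
                "reduce n_svs / SV sizes"
            )

    # --- genotypes ---------------------------------------------------------
    gt = np.empty((n, len(ind)), dtype=np.int8)
    for j in range(n):
        gt[j] = _draw_pattern(rng, states[j], sub, config.missing_rate)

    # --- repeat track: co-placed repeats + decoys --------------------------
    # The co-placed repeat covers its SV's whole effective interval, so the
    # truth REP type always has the maximal possible overlap; decoys avoid
    # every SV interval, so non-repeat SVs stay repeat-free and dominant
    # types stay exact.
    feats = []
    for j in range(n):
        if not is_rep[j]:
            continue
        s0 = int(pos[j] - 1)
        e0 = s0 + int(svlen[j])
        feats.append(RepeatFeature(names[chrom_idx[j]], s0, e0, str(rep_type[j])))

    def _clear_of_svs(c, rs, re_):
        iv = booked[c]
        i = bisect.bisect_left(iv, (re_, re_))
        return not (i > 0 and iv[i - 1][1] > rs)

    for ci, (cname, clen) in enumerate(genome.chromosomes):
        k = rng.poisson(config.decoy_repeats_per_mb * clen / 1e6)
        for _ in range(k):
            rlen = int(rng.integers(100, 3000))
            t = type_names[rng.choice(len(type_names), p=type_w)]
            for _attempt in range(50):
                rs = int(rng.integers(0, max(clen - rlen, 1)))
                if _clear_of_svs(ci, rs, rs + rlen):
                    feats.append(RepeatFeature(cname, rs, rs + rlen, t))
                    break

    repeats = RepeatTrack(feats)

    # --- genes -------------------------------------------------------------
    gfeats = []
    gid = 0
    for cname, clen in genome.chromosomes:
        k = rng.poisson(config.genes_per_mb * clen / 1e6)
        for _ in range(k):
            gid += 1
            glen = int(rng.integers(5_000, 50_000))
            gs = int(rng.integers(0, max(clen - glen, 1)))
            strand = "+" if rng.random() < 0.5 else "-"
            name_g = f"gene{gid:04d}"
            gfeats.append(GeneFeature(cname, gs, gs + glen, "gene", name_g, strand))
            for _e in range(config.exons_per_gene):
                elen = int(rng.integers(100, max(glen // config.exons_per_gene, 101)))
                es = int(rng.integers(gs, max(gs + glen - elen, gs + 1)))
                gfeats.append(GeneFeature(cname, es, min(es + elen, gs + glen), "exon", name_g, strand))
    genes = GeneTrack(gfeats)

    # --- records, truth ----------------------------------------------------
    order = np.lexsort((pos, np.array([names[c] for c in chrom_idx])))
    records = []
    truth_rows = []
    for rank, j in enumerate(order):
        cname = names[chrom_idx[j]]
        sid = f"sv{rank:06d}"
        end = int(pos[j]) if svtypes[j] == "INS" else int(pos[j] + svlen[j] - 1)
        records.append(
            SVRecord(cname, int(pos[j]), end, str(svtypes[j]), int(svlen[j]), sid,
                     gt[j].copy(), frozenset({"simulated"}), "simulated")
        )
        L = svlen[j]
        truth_rows.append(
            {
                "sv_id": sid,
                "chrom": cname,
                "pos": int(pos[j]),
                "svtype": str(svtypes[j]),
                "svlen": int(L),
                "state": str(states[j]),
                "is_rep": bool(is_rep[j]),
                "rep_type": str(rep_type[j]) if is_rep[j] else "",
                "on_x": cname == genome.x_name,
                "size_class": "small" if L < 200 else ("medium" if L < 500 else "large"),
            }
        )
    truth = pd.DataFrame(truth_rows)
    cohort = SVCallSet(list(metadata["individual"]), records, source="simulated-cohort")

    callsets = []
    for i, name_i in enumerate(metadata["individual"]):
        recs = [
            SVRecord(r.chrom, r.pos, r.end, r.svtype, r.svlen, r.id,
                     np.array([r.genotypes[i]], dtype=np.int8),
                     frozenset({name_i}), name_i)
            for r in cohort.records
            if r.genotypes[i] > 0
        ]
        callsets.append(SVCallSet([name_i], recs, source=name_i))

    return CohortSim(cohort, callsets, repeats, genes, metadata, truth, genome, config)


def write_cohort(sim: CohortSim, outdir) -> None:
    """Write a simulated cohort in its interchange formats (VCF/BED/.out/GFF3/TSV)."""
    from pathlib import Path
    from .sv_io import write_gene_annotation, write_repeat_annotation, write_sv_vcf

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    contigs = list(sim.genome.chromosomes)
    write_sv_vcf(sim.cohort, out / "cohort.vcf", contigs=contigs)
    for cs in sim.callsets:
        write_sv_vcf(cs, out / f"{cs.source}.vcf", contigs=contigs)
    write_repeat_annotation(sim.repeats, out / "repeats.bed", "bed")
    write_repeat_annotation(sim.repeats, out / "repeats.out", "rmout")
    write_gene_annotation(sim.genes, out / "genes.gff3")
    sim.metadata.to_csv(out / "samples.tsv", sep="\t", index=False)
    sim.truth.to_csv(out / "truth.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# focused generators for the statistical modules
# ---------------------------------------------------------------------------

def simulate_regression_data(model_name: str, params, n: int, noise_sd: float,
                             seed: int, x_range=None):
    """(x, y) pairs from one of the nine candidate models plus Gaussian noise."""
    spec = model_select.MODELS[model_name]
    if x_range is None:
        x_range = (1.0, 10.0) if spec.positive_x else (0.0, 10.0)
    lo, hi = x_range
    if spec.positive_x and lo <= 0:
        raise ValueError(f"{model_name} requires x > 0")
    x = np.linspace(lo, hi, n)
    rng = np.random.default_rng(seed)
    y = spec.func(x, *params) + rng.normal(0.0, noise_sd, size=n)
    return x, y


#: representative parameter values used in the model-recovery study
RECOVERY_PARAMS = {
    "Linear": (1.0, 2.0),
    "Inverse": (1.0, 5.0),
    "Logarithmic": (1.0, 3.0),
    "Quadratic": (1.0, 0.5, 0.3),
    "InverseAndLinear": (1.0, 5.0, 2.0),
    "ConstantAndLogarithmic": (2.0, 3.0),
    "InverseAndConstant": (2.0, 4.0),
    "Exponential": (1.5, 0.35),
    "Power": (2.0, 1.6),
}


def model_recovery_study(n_seeds: int = 100, n: int = 50, snr: float = 10.0,
                         seed: int = 0):
    """Simulate-and-refit study of AIC model selection.

    For every candidate model, ``n_seeds`` datasets of ``n`` points are
    simulated at signal-to-noise ``snr`` (sd of the noise = sd of the signal
    / snr) and all nine models are fitted; selection is correct when the
    AIC-best model can represent the generating curve exactly
    (:func:`repsv.model_select.nesting_models` — this folds in the two
    re-parameterised aliases).  Returns (confusion matrix generating x
    selected, per-model success-rate Series).
    """
    names = list(model_select.MODELS)
    confusion = pd.DataFrame(0, index=names, columns=names)
    base = np.random.default_rng(seed).integers(0, 2**31 - 1, size=len(names))
    for gi, gen in enumerate(names):
        params = RECOVERY_PARAMS[gen]
        spec = model_select.MODELS[gen]
        x0 = np.linspace(1.0, 10.0, n) if spec.positive_x else np.linspace(0.0, 10.0, n)
        noise = float(np.std(spec.func(x0, *params)) / snr)
        for s in range(n_seeds):
            x, y = simulate_regression_data(
                gen, params, n, noise, seed=int((base[gi] + s) % (2**31 - 1))
            )
            best, _ = model_select.select_best(model_select.fit_all(x, y))
            confusion.loc[gen, best.name] += 1
    success = pd.Series(
        {
            g: sum(confusion.loc[g, m] for m in model_select.nesting_models(g)) / n_seeds
            for g in names
        }
    )
    return confusion, success


def simulate_composition(n_individuals: int, n_types: int, structure="uniform",
                         seed: int = 0, total: int = 1000) -> pd.DataFrame:
    """Individuals x REP-type count matrix, uniform or dominated by one type.

    ``structure`` is ``"uniform"`` or ``("dominated", type_index, share)``
    with ``share`` in (0, 1): the dominated type's expected proportion.
    """
    if n_types < 2:
        raise ValueError("n_types must be >= 2")
    if structure == "uniform":
        p = np.full(n_types, 1.0 / n_types)
    else:
        kind, t, share = structure
        if kind != "dominated":
            raise ValueError(f"unknown structure {structure!r}")
        if not (0 < share < 1):
            raise ValueError("share must be in (0, 1)")
        p = np.full(n_types, (1.0 - share) / (n_types - 1))
        p[t] = share
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(total, p, size=n_individuals)
    return pd.DataFrame(
        counts,
        index=[f"ind{i + 1}" for i in range(n_individuals)],
        columns=[f"type{j + 1}" for j in range(n_types)],
    )


def simulate_fst_genotypes(F: float, n_sites: int, n_per_group: int, seed: int):
    """Balding–Nichols two-population genotypes for F_ST calibration.

    Ancestral frequencies are Uniform(0.1, 0.9); each population's frequency
    is Beta(p(1−F)/F, (1−p)(1−F)/F); genotypes are Binomial(2, freq).
    Returns (genotype matrix sites x individuals, group labels).
    """
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.9, size=n_sites)
    a, b = p * (1 - F) / F, (1 - p) * (1 - F) / F
    p1 = rng.beta(a, b)
    p2 = rng.beta(a, b)
    g1 = rng.binomial(2, p1[:, None], size=(n_sites, n_per_group))
    g2 = rng.binomial(2, p2[:, None], size=(n_sites, n_per_group))
    geno = np.concatenate([g1, g2], axis=1).astype(np.int8)
    groups = np.array(["pop1"] * n_per_group + ["pop2"] * n_per_group)
    return geno, groups
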