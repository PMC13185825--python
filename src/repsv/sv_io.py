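"""Reading, writing and merging of structural-variant call sets and annotation tracks.

Internal coordinate policy: every interval that lives inside this package is
0-based half-open.  VCF (1-based, inclusive END), RepeatMasker ``.out``
(1-based inclusive) and GFF3 (1-based inclusive) are converted at the I/O
boundary; BED is already 0-based half-open.

Genotypes are stored as diploid alternate-allele counts per sample
(``-1`` missing, ``0`` absent, ``1``/``2`` present), the coding of a VCF GT
field with one symbolic ALT allele.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pyranges as pr
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

SV_TYPES = ("INS", "DEL", "DUP", "INV")

MISSING = -1


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SVRecord:
    """One structural variant.

    ``pos``/``end`` follow the VCF convention (1-based, inclusive end).  For
    insertions the stored ``end`` equals ``pos``; the effective interval used
    for overlap arithmetic is computed downstream (annotate.effective_interval).
    """

    chrom: str
    pos: int
    end: int
    svtype: str
    svlen: int
    id: str = "."
    genotypes: np.ndarray | None = None  # alt-allele counts aligned to the call set's samples
    support: frozenset = frozenset()
    source: str = ""

    def presence(self) -> np.ndarray | None:
        """Per-sample presence: 1 present, 0 absent, -1 missing."""
        if self.genotypes is None:
            return None
        g = np.asarray(self.genotypes)
        out = np.where(g == MISSING, MISSING, (g > 0).astype(np.int8))
        return out


@dataclass
class SVCallSet:
    samples: list[str]
    records: list[SVRecord]
    source: str = ""

    def __post_init__(self):
        self.records = sorted(self.records, key=lambda r: (r.chrom, r.pos, r.end, r.id))

    def __len__(self):
        return len(self.records)

    def presence_matrix(self) -> np.ndarray:
        """(n_records, n_samples) presence matrix; -1 marks missing calls."""
        return np.array([r.presence() for r in self.records], dtype=np.int8)

    def genotype_matrix(self) -> np.ndarray:
        return np.array([r.genotypes for r in self.records], dtype=np.int8)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]


@dataclass(frozen=True)
class RepeatFeature:
    chrom: str
    start: int  # 0-based
    end: int    # half-open
    rep_type: str

    def __post_init__(self):
        if not (self.start < self.end):
            raise ValueError(f"inverted repeat interval {self.chrom}:{self.start}-{self.end}")
        if not self.rep_type:
            raise ValueError("empty rep_type")


class RepeatTrack:
    """Interval-indexed collection of repeat annotations."""

    def __init__(self, features):
        self.features = list(features)
        self._df = pd.DataFrame(
            {
                "Chromosome": [f.chrom for f in self.features],
                "Start": [f.start for f in self.features],
                "End": [f.end for f in self.features],
                "rep_type": [f.rep_type for f in self.features],
            }
        )

    def __len__(self):
        return len(self.features)

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    def to_pyranges(self) -> pr.PyRanges:
        return pr.PyRanges(self._df.copy())


@dataclass(frozen=True)
class GeneFeature:
    chrom: str
    start: int
    end: int
    kind: str  # gene | exon
    gene_id: str
    strand: str = "+"


class GeneTrack:
    def __init__(self, features):
        self.features = list(features)
        for f in self.features:
            if f.kind not in ("gene", "exon"):
                raise ValueError(f"unknown feature kind {f.kind}")
        self._df = pd.DataFrame(
            {
                "Chromosome": [f.chrom for f in self.features],
                "Start": [f.start for f in self.features],
                "End": [f.end for f in self.features],
                "kind": [f.kind for f in self.features],
                "gene_id": [f.gene_id for f in self.features],
                "Strand": [f.strand for f in self.features],
            }
        )

    def __len__(self):
        return len(self.features)

    @property
    def df(self):
        return self._df


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_sv_vcf(path) -> SVCallSet:
    """Read an SV VCF into an :class:`SVCallSet`.

    Records need SVTYPE plus at least one of SVLEN/END to be resolvable;
    records with neither are skipped with a warning, as are unsupported
    SVTYPEs (e.g. BND).  SVLEN is stored as an absolute value.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records = []
    n_skipped_type = n_skipped_len = 0
    for v in vcf:
        svtype = v.INFO.get("SVTYPE")
        if svtype not in SV_TYPES:
            n_skipped_type += 1
            continue
        svlen = v.INFO.get("SVLEN")
        end = v.INFO.get("END")
        if svlen is None and end is None:
            n_skipped_len += 1
            continue
        pos = v.POS
        if svlen is None:
            svlen = 0 if svtype == "INS" else end - pos + 1
        svlen = abs(int(svlen))
        if svtype == "INS":
            end = pos
        elif end is None:
            end = pos + svlen - 1
        if samples:
            gt = np.empty(len(samples), dtype=np.int8)
            for i, t in enumerate(v.gt_types):
                # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
                gt[i] = MISSING if t == 2 else (0 if t == 0 else (1 if t == 1 else 2))
        else:
            gt = None
        records.append(
            SVRecord(v.CHROM, pos, int(end), svtype, svlen, v.ID or ".", gt)
        )
    if n_skipped_type or n_skipped_len:
        logger.warning(
            "%s: skipped %d records with unsupported SVTYPE, %d without SVLEN/END",
            path, n_skipped_type, n_skipped_len,
        )
    cs = SVCallSet(samples, records, source=str(path))
    cs.n_skipped = n_skipped_type + n_skipped_len
    return cs


_GT_STR = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_sv_vcf(callset: SVCallSet, path, contigs=None) -> None:
    """Write an SVCallSet as VCF 4.2 with symbolic ALT alleles."""
    if contigs is None:
        seen = {}
        for r in callset.records:
            seen[r.chrom] = max(seen.get(r.chrom, 0), r.end, r.pos + r.svlen)
        contigs = [(c, int(l)) for c, l in seen.items()]
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position (1-based inclusive)">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    lines += [f"##contig=<ID={c},length={l}>" for c, l in contigs]
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if callset.samples:
        header += ["FORMAT"] + list(callset.samples)
    lines.append("\t".join(header))
    for r in callset.records:
        svlen = -r.svlen if r.svtype == "DEL" else r.svlen
        info = f"SVTYPE={r.svtype};SVLEN={svlen};END={r.end}"
        row = [r.chrom, str(r.pos), r.id, "N", f"<{r.svtype}>", ".", "PASS", info]
        if callset.samples:
            row.append("GT")
            row += [_GT_STR[int(g)] for g in r.genotypes]
        lines.append("\t".join(row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# repeat / gene annotation formats
# ---------------------------------------------------------------------------

_RMOUT_HEADER = (
    "   SW  perc perc perc  query      position in query           matching"
    "       repeat              position in  repeat\n"
    "score  div. del. ins.  sequence    begin     end    (left)    repeat"
    "         class/family         begin  end (left)   ID\n"
    "\n"
)


def read_repeat_annotation(path, dialect: str) -> RepeatTrack:
    """Read repeat features from BED (``bed``) or RepeatMasker ``.out`` (``rmout``)."""
    feats = []
    if dialect == "bed":
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split()
                chrom, start, end = f[0], int(f[1]), int(f[2])
                name = f[3] if len(f) > 3 else "repeat"
                if start < 0 or start >= end:
                    raise ValueError(f"{path}:{ln}: bad interval {start}-{end}")
                feats.append(RepeatFeature(chrom, start, end, name))
    elif dialect == "rmout":
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                f = line.split()
                if not f or not f[0][0].isdigit():
                    continue  # header / blank lines
                chrom, begin, end = f[4], int(f[5]), int(f[6])
                rep_type = f[10]
                if begin < 1 or begin > end:
                    raise ValueError(f"{path}:{ln}: bad interval {begin}-{end}")
                feats.append(RepeatFeature(chrom, begin - 1, end, rep_type))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return RepeatTrack(feats)


def write_repeat_annotation(track: RepeatTrack, path, dialect: str) -> None:
    if dialect == "bed":
        with open(path, "w") as fh:
            for i, f in enumerate(track.features):
                fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.rep_type}\t0\t+\n")
    elif dialect == "rmout":
        with open(path, "w") as fh:
            fh.write(_RMOUT_HEADER)
            for i, f in enumerate(track.features):
                fh.write(
                    f"  500  1.0  0.0  0.0  {f.chrom}  {f.start + 1}  {f.end}  (0)  +"
                    f"  {f.rep_type.split('/')[-1]}  {f.rep_type}  1  {f.end - f.start}  (0)  {i + 1}\n"
                )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_gene_annotation(path) -> GeneTrack:
    """Read gene/exon features from GFF3 (1-based inclusive -> half-open)."""
    feats = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ValueError(f"{path}:{ln}: not GFF3")
            kind = f[2]
            if kind not in ("gene", "exon"):
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            gid = attrs.get("gene_id") or attrs.get("ID") or attrs.get("Parent", ".")
            feats.append(GeneFeature(f[0], int(f[3]) - 1, int(f[4]), kind, gid, f[6]))
    return GeneTrack(feats)


def write_gene_annotation(track: GeneTrack, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in track.features:
            attr = f"ID={f.gene_id}" if f.kind == "gene" else f"Parent={f.gene_id}"
            attr += f";gene_id={f.gene_id}"
            fh.write(
                f"{f.chrom}\trepsv\t{f.kind}\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\t{attr}\n"
            )


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def _lower_median(values) -> int:
    v = sorted(values)
    return v[(len(v) - 1) // 2]


def merge_callsets(
    callsets,
    max_dist: int = 1000,
    min_support: int = 2,
    require_type_match: bool = True,
    min_len: int = 50,
    max_len: int = 100_000,
) -> SVCallSet:
    """SURVIVOR-style merge of several call sets.

    Records are clustered per chromosome (and per SV type when
    ``require_type_match``) by single linkage, with an edge between two
    records when both their start and their end coordinates are within
    ``max_dist`` bp.  Clusters supported by fewer than ``min_support``
    distinct sources are dropped, as are merged records outside
    ``[min_len, max_len]``.

    The merged record is the cluster member with the smallest
    ``(chrom, pos, end, source)`` tuple; its length is the lower median of
    member lengths.  Genotypes are combined across call sets per sample
    (maximum alternate-allele count; a sample absent from every contributing
    call set stays absent).
    """
    if not callsets:
        raise ValueError("need at least one call set")
    samples: list[str] = []
    for cs in callsets:
        for s in cs.samples:
            if s not in samples:
                samples.append(s)
    tagged = []  # (record, source, sample_index_map)
    for ci, cs in enumerate(callsets):
        src = cs.source or f"callset{ci}"
        idx = [samples.index(s) for s in cs.samples]
        for r in cs.records:
            tagged.append((r, src, idx))

    groups: dict = {}
    for item in tagged:
        r = item[0]
        key = (r.chrom, r.svtype) if require_type_match else (r.chrom,)
        groups.setdefault(key, []).append(item)

    merged_records = []
    for key, items in groups.items():
        items.sort(key=lambda it: (it[0].pos, it[0].end))
        n = len(items)
        parent = list(range(n))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        def union(a, b):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra

        for i in range(n):
            ri = items[i][0]
            j = i + 1
            while j < n and items[j][0].pos - ri.pos <= max_dist:
                if abs(items[j][0].end - ri.end) <= max_dist:
                    union(i, j)
                j += 1
        clusters: dict = {}
        for i in range(n):
            clusters.setdefault(find(i), []).append(items[i])
        for members in clusters.values():
            support = frozenset().union(
                *[m[0].support or frozenset([m[1]]) for m in members]
            )
            if len(support) < min_support:
                continue
            svlen = _lower_median([m[0].svlen for m in members])
            if not (min_len <= svlen <= max_len):
                continue
            rep = min(members, key=lambda m: (m[0].chrom, m[0].pos, m[0].end, m[1]))
            gt = np.zeros(len(samples), dtype=np.int8) if samples else None
            if gt is not None:
                touched = np.zeros(len(samples), dtype=bool)
                anymiss = np.zeros(len(samples), dtype=bool)
                for rec, _src, idx in members:
                    if rec.genotypes is None:
                        continue
                    for k, si in enumerate(idx):
                        g = int(rec.genotypes[k])
                        if g == MISSING:
                            anymiss[si] = True
                        else:
                            gt[si] = max(gt[si], g)
                            touched[si] = True
                gt[(~touched) & anymiss] = MISSING
            merged_records.append(
                replace(rep[0], svlen=svlen, genotypes=gt, support=support, source=rep[1])
            )
    return SVCallSet(samples, merged_records, source="merged")


def filter_missingness(
    callset: SVCallSet, max_missing: float = 0.5, drop_all_absent: bool = False
) -> SVCallSet:
    """Drop SVs whose missing-genotype fraction exceeds ``max_missing`` (strict >).

    With ``drop_all_absent`` SVs with no present genotype in any individual
    are removed as well (the unreliable-genotype rule).
    """
    if not callset.samples:
        raise ValueError("call set has no genotypes")
    kept = []
    for r in callset.records:
        p = r.presence()
        miss = float(np.mean(p == MISSING))
        if miss > max_missing:
            continue
        if drop_all_absent and not np.any(p == 1):
            continue
        kept.append(r)
    return SVCallSet(callset.samples, kept, source=callset.source)


# ---------------------------------------------------------------------------
# novelty partition
# ---------------------------------------------------------------------------

def _effective_bounds(r: SVRecord):
    # mirror annotate.effective_interval without the import cycle
    if r.svtype == "INS":
        return r.pos - 1, r.pos - 1 + r.svlen
    return r.pos - 1, r.end


def novelty_filter(callset: SVCallSet, published: SVCallSet, reciprocal_frac: float = 0.5):
    """Partition a call set into (novel, known) against a published set.

    An SV is *known* when some published SV (of any type) overlaps it by at
    least ``reciprocal_frac`` of both SVs' effective lengths; insertions use
    the start + insertion-length effective interval.
    """
    pub = {}
    for r in published.records:
        s, e = _effective_bounds(r)
        pub.setdefault(r.chrom, []).append((s, e))
    novel, known = [], []
    for r in callset.records:
        s, e = _effective_bounds(r)
        qlen = e - s
        hit = False
        for ps, pe in pub.get(r.chrom, ()):
            ov = min(e, pe) - max(s, ps)
            plen = pe - ps
            if qlen > 0 and plen > 0 and ov >= reciprocal_frac * qlen and ov >= reciprocal_frac * plen:
                hit = True
                break
        (known if hit else novel).append(r)
    return (
        SVCallSet(callset.samples, novel, source="novel"),
        SVCallSet(callset.samples, known, source="known"),
    )


# ---------------------------------------------------------------------------
# saturation
# ---------------------------------------------------------------------------

def _identity_key(r: SVRecord):
    if r.id not in (".", "", None):
        return r.id
    return (r.chrom, r.pos, r.end, r.svtype, r.svlen)


def saturation_curve(callsets, n_reps: int, seed: int) -> pd.DataFrame:
    """Pan-SV saturation by subsampling individuals.

    For each cohort size k, ``n_reps`` random orderings (without replacement)
    of the call sets are drawn; the cumulative union ("pan") and intersection
    ("core") of SV identities along each ordering are recorded.  Identity is
    the SV id when present (call sets produced by this pipeline share a
    pan-SV id namespace), else the coordinate tuple.
    """
    if len(callsets) < 2:
        raise ValueError("need at least 2 call sets")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    keysets = [frozenset(_identity_key(r) for r in cs.records) for cs in callsets]
    n = len(keysets)
    pan = np.zeros((n_reps, n))
    core = np.zeros((n_reps, n))
    for rep in range(n_reps):
        order = rng.permutation(n)
        u = set()
        c = None
        for k, i in enumerate(order):
            u |= keysets[i]
            c = set(keysets[i]) if c is None else (c & keysets[i])
            pan[rep, k] = len(u)
            core[rep, k] = len(c)
    return pd.DataFrame(
        {
            "k": np.arange(1, n + 1),
            "pan_mean": pan.mean(axis=0),
            "pan_sd": pan.std(axis=0, ddof=0),
            "core_mean": core.mean(axis=0),
            "core_sd": core.std(axis=0, ddof=0),
        }
    )
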