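"""GGAA-microsatellite and ETS-motif discovery and gene classification.

The fusion factor binds two kinds of response element: repetitive
GGAA-microsatellites (promoter-like when < 5 kb from a transcription start
site, enhancer-like when farther) and high-affinity ETS sites with consensus
5'-ACMGGAARY-3'.  This module scans nucleotide sequence for both, measures
element-to-TSS distances, and assigns every gene to a single
response-element class crossed with its endogenous regulation direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IUPAC",
    "ScanParams",
    "reverse_complement",
    "find_ggaa_microsatellites",
    "scan_ets_motif",
    "element_gene_distance",
    "assign_response_classes",
    "compare_element_features",
]

IUPAC: dict[str, frozenset] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "M": frozenset("AC"), "K": frozenset("GT"),
    "S": frozenset("CG"), "W": frozenset("AT"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGTN"),  # N in sequence only matches pattern N
}

_COMPLEMENT = str.maketrans("ACGTRYMKSWBDHVN", "TGCAYRKMSWVHDBN")

GENE_CLASSES = (
    "ms_enh_act", "ms_prom_act", "ms_enh_rep", "ms_prom_rep",
    "ets_direct", "other_fli_direct", "none",
)


def reverse_complement(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class ScanParams:
    """Scanning and classification thresholds.

    ``distance_threshold`` splits promoter-like (strictly closer) from
    enhancer-like microsatellites; ``direct_window_up``/``down`` bound the
    strand-aware window around the TSS used for non-microsatellite direct
    targets; ``association_radius`` caps how far a microsatellite may sit
    from a TSS and still be linked to the gene.  The minimum repeat count
    and merge gap of the microsatellite caller are explicit stand-ins: the
    localization studies the element taxonomy derives from do not publish a
    portable definition.
    """

    min_repeats: int = 4
    max_gap: int = 4
    ets_motif: str = "ACMGGAARY"
    distance_threshold: int = 5000
    direct_window_up: int = 5000
    direct_window_down: int = 1000
    scan_both_strands: bool = True
    association_radius: int = 500_000
    alpha: float = 0.05

    def validate(self) -> None:
        for name in ("min_repeats", "max_gap", "distance_threshold",
                     "direct_window_up", "direct_window_down", "association_radius"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        bad = [c for c in self.ets_motif.upper() if c not in IUPAC]
        if bad or not self.ets_motif:
            raise ValueError(f"ets_motif is not valid IUPAC: {self.ets_motif!r}")


def _validate_seq(seq: str) -> str:
    seq = seq.upper()
    allowed = frozenset("ACGTN")
    if not set(seq) <= allowed:
        for i, ch in enumerate(seq):
            if ch not in allowed:
                raise ValueError(f"non-IUPAC character {ch!r} at position {i}")
    return seq


def _unit_positions(seq: str, unit: str) -> list[int]:
    """Start positions of every occurrence of ``unit`` (C-speed str.find)."""
    out = []
    i = seq.find(unit)
    while i != -1:
        out.append(i)
        i = seq.find(unit, i + 1)
    return out


def _runs(seq: str, unit: str) -> list[tuple[int, int]]:
    """Maximal runs of back-to-back units: (start, n_units)."""
    runs = []
    for p in _unit_positions(seq, unit):
        if runs and p == runs[-1][0] + 4 * runs[-1][1]:
            runs[-1] = (runs[-1][0], runs[-1][1] + 1)
        elif runs and p < runs[-1][0] + 4 * runs[-1][1]:
            continue  # occurrence inside the current run (overlapping frame)
        else:
            runs.append((p, 1))
    return runs


def _call_strand(seq: str, unit: str, strand: str, params: ScanParams,
                 chrom: str) -> list[dict]:
    runs = _runs(seq, unit)
    merged: list[list] = []  # [start, end, total, max_consecutive]
    for start, n_units in runs:
        end = start + 4 * n_units
        if merged and start - merged[-1][1] <= params.max_gap:
            merged[-1][1] = end
            merged[-1][2] += n_units
            merged[-1][3] = max(merged[-1][3], n_units)
        else:
            merged.append([start, end, n_units, n_units])
    return [
        {"chrom": chrom, "start": s, "end": e, "strand": strand,
         "type": "ggaa_ms", "max_consecutive": mx, "total_repeats": tot,
         "fli_enrichment": np.nan}
        for s, e, tot, mx in merged
        if tot >= params.min_repeats
    ]


def find_ggaa_microsatellites(seq: str, params: ScanParams | None = None,
                              chrom: str = "chr") -> pd.DataFrame:
    """Call GGAA-microsatellites in a nucleotide string.

    Maximal runs of consecutive ``GGAA`` units are found on the plus strand
    (and ``TTCC`` runs reported as minus-strand elements when
    ``scan_both_strands``); runs separated by at most ``max_gap`` non-motif
    bases are merged into one element; elements with fewer than
    ``min_repeats`` total units are dropped.  Coordinates are 0-based
    half-open.
    """
    params = params or ScanParams()
    params.validate()
    seq = _validate_seq(seq)
    rows = _call_strand(seq, "GGAA", "+", params, chrom)
    if params.scan_both_strands:
        rows += _call_strand(seq, "TTCC", "-", params, chrom)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "type",
                                     "max_consecutive", "total_repeats", "fli_enrichment"])
    return df.sort_values(["start", "strand"], kind="stable").reset_index(drop=True)


def _iupac_match_positions(seq: str, motif: str) -> np.ndarray:
    """All start positions where ``motif`` (IUPAC) matches ``seq`` exactly."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    L = len(motif)
    if len(arr) < L:
        return np.empty(0, dtype=int)
    ok = np.ones(len(arr) - L + 1, dtype=bool)
    for off, ch in enumerate(motif):
        lut = np.zeros(256, dtype=bool)
        for c in IUPAC[ch]:
            lut[ord(c)] = True
        ok &= lut[arr[off:off + len(ok)]]
    return np.flatnonzero(ok)


def scan_ets_motif(seq: str, params: ScanParams | None = None,
                   chrom: str = "chr") -> pd.DataFrame:
    """Scan for the high-affinity ETS consensus (default 5'-ACMGGAARY-3').

    The plus strand is matched against the motif itself and, when
    ``scan_both_strands``, the minus strand via the motif's reverse
    complement matched on the given text.  Overlapping matches are all
    reported.
    """
    params = params or ScanParams()
    params.validate()
    seq = _validate_seq(seq)
    motif = params.ets_motif.upper()
    rows = []
    for strand, pat in (("+", motif), ("-", reverse_complement(motif))):
        if strand == "-" and not params.scan_both_strands:
            continue
        for p in _iupac_match_positions(seq, pat):
            rows.append({"chrom": chrom, "start": int(p), "end": int(p) + len(pat),
                         "strand": strand, "type": "ets_motif",
                         "max_consecutive": 1, "total_repeats": 1,
                         "fli_enrichment": np.nan})
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "type",
                                     "max_consecutive", "total_repeats", "fli_enrichment"])
    return df.sort_values(["start", "strand"], kind="stable").reset_index(drop=True)


def element_gene_distance(start: int, end: int, tss: int) -> int:
    """Unsigned bp from the nearest element edge to the TSS.

    Zero when the TSS lies inside the half-open element interval.  The
    half-open ``end`` is used directly as the downstream edge, so a TSS at
    ``end`` is at distance 0.
    """
    if end <= start:
        raise ValueError("element end must exceed start")
    if tss < start:
        return start - tss
    if tss >= end:
        return tss - end
    return 0


def _distances(starts: np.ndarray, ends: np.ndarray, tss: int) -> np.ndarray:
    return np.maximum.reduce([starts - tss, tss - ends, np.zeros(len(starts), dtype=int)])


def assign_response_classes(genes: pd.DataFrame, elements: pd.DataFrame,
                            endo: pd.DataFrame,
                            params: ScanParams | None = None) -> pd.DataFrame:
    """Assign each gene to exactly one response-element class.

    For genes significantly regulated in the endogenous profile
    (``padj < alpha``): the nearest GGAA-microsatellite on the same
    chromosome within ``association_radius`` gives a promoter-like
    (distance strictly below ``distance_threshold``) or enhancer-like class,
    crossed with the endogenous direction; genes with no microsatellite but
    an ETS motif (or, failing that, another factor-bound element) overlapping
    the strand-aware window ``[TSS - up, TSS + down)`` fall in the direct
    classes.  Everything else, including endo-non-significant genes, is
    ``none``.  Precedence: microsatellite > ETS motif > other bound element.

    Parameters
    ----------
    genes : DataFrame(chrom, tss, strand, gene)
    elements : DataFrame with at least (chrom, start, end, type); types are
        ``ggaa_ms``, ``ets_motif``, ``other_fli``.
    endo : DE table of the endogenous contrast (gene, log2fc, padj).

    Returns
    -------
    DataFrame(gene, element_class, element_id, distance)
    """
    import logging

    params = params or ScanParams()
    params.validate()
    endo_idx = endo.set_index("gene")
    elements = elements.copy()
    if "element_id" not in elements.columns:
        elements["element_id"] = [f"e{i:05d}" for i in range(len(elements))]

    by_chrom_type: dict[tuple[str, str], pd.DataFrame] = {
        k: v.reset_index(drop=True) for k, v in elements.groupby(["chrom", "type"])
    }

    rows = []
    log = logging.getLogger(__name__)
    for rec in genes.itertuples(index=False):
        gene, chrom, tss, strand = rec.gene, rec.chrom, int(rec.tss), rec.strand
        if gene not in endo_idx.index:
            log.warning("gene %s absent from endogenous DE table; class none", gene)
            rows.append((gene, "none", None, np.nan))
            continue
        padj = endo_idx.at[gene, "padj"]
        lfc = endo_idx.at[gene, "log2fc"]
        if not (pd.notna(padj) and padj < params.alpha):
            rows.append((gene, "none", None, np.nan))
            continue
        direction = "act" if lfc >= 0 else "rep"

        ms = by_chrom_type.get((chrom, "ggaa_ms"))
        if ms is not None and len(ms):
            d = _distances(ms["start"].to_numpy(), ms["end"].to_numpy(), tss)
            order = np.lexsort((ms["start"].to_numpy(), d))
            best = order[0]
            if d[best] <= params.association_radius:
                kind = "ms_prom" if d[best] < params.distance_threshold else "ms_enh"
                rows.append((gene, f"{kind}_{direction}",
                             ms.at[best, "element_id"], int(d[best])))
                continue

        if strand == "-":
            win_lo, win_hi = tss - params.direct_window_down, tss + params.direct_window_up
        else:
            win_lo, win_hi = tss - params.direct_window_up, tss + params.direct_window_down
        hit = None
        for etype, klass in (("ets_motif", "ets_direct"), ("other_fli", "other_fli_direct")):
            cand = by_chrom_type.get((chrom, etype))
            if cand is None or not len(cand):
                continue
            overlap = (cand["start"].to_numpy() < win_hi) & (cand["end"].to_numpy() > win_lo)
            if overlap.any():
                d = _distances(cand["start"].to_numpy(), cand["end"].to_numpy(), tss)
                d = np.where(overlap, d, np.iinfo(np.int64).max)
                best = int(np.lexsort((cand["start"].to_numpy(), d))[0])
                hit = (gene, klass, cand.at[best, "element_id"], int(d[best]))
                break
        rows.append(hit if hit is not None else (gene, "none", None, np.nan))

    return pd.DataFrame(rows, columns=["gene", "element_class", "element_id", "distance"])


def compare_element_features(group_a: pd.DataFrame, group_b: pd.DataFrame,
                             features: tuple = ("max_consecutive", "total_repeats",
                                                "fli_enrichment")) -> pd.DataFrame:
    """Compare element feature distributions between two element groups.

    For each feature the two group medians and a two-sample Mann-Whitney U
    test (normal approximation with tie correction, no continuity
    correction) are reported.  Features absent (all-NaN) in either group are
    skipped with a note.
    """
    if not len(group_a) or not len(group_b):
        raise ValueError("both element groups must be non-empty")
    rows = []
    for feat in features:
        a = group_a[feat].dropna().to_numpy() if feat in group_a else np.empty(0)
        b = group_b[feat].dropna().to_numpy() if feat in group_b else np.empty(0)
        if not len(a) or not len(b):
            rows.append((feat, np.nan, np.nan, np.nan, np.nan, "skipped: feature absent"))
            continue
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided",
                                  method="asymptotic", use_continuity=False)
        rows.append((feat, float(np.median(a)), float(np.median(b)),
                     float(u), float(p), ""))
    return pd.DataFrame(rows, columns=["feature", "median_a", "median_b",
                                       "statistic", "p", "note"])
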