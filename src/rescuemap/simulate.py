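"""Synthetic knockdown/rescue RNA-seq experiments with planted ground truth.

The generator emulates the design of a shRNA knockdown/rescue study of a
fusion transcription factor: an ``iLuc`` control (endogenous factor intact),
an ``iEF`` knockdown condition used as the reference for every contrast, and
one or more rescue constructs re-expressed on the knockdown background.
Counts are negative-binomial with per-gene baseline and dispersion, per-batch
location/scale effects, and per-sample library-size variation.  A companion
annotation simulator plants GGAA-microsatellites and high-affinity ETS motifs
on a synthetic genome so that sequence scanning, distance classification and
class-stratified rescue summaries can be tested end to end against known
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConstructEffect",
    "ElementConfig",
    "SimConfig",
    "SimTruth",
    "simulate_experiment",
    "simulate_annotation",
]

ENDO_CLASSES = ("activated", "repressed", "null")

#: element classes a gene can be planted into (mirrors the response-element
#: taxonomy used downstream: promoter-like / enhancer-like microsatellite and
#: high-affinity ETS direct targets)
ELEMENT_CLASSES = ("ms_promoter", "ms_enhancer", "ets", "none")


@dataclass
class ConstructEffect:
    """Planted behaviour of one rescue construct.

    Parameters
    ----------
    rescue_frac :
        Fraction of endogenously regulated genes this construct rescues
        (regulates significantly, in either direction).  Either a scalar
        applied to every element class, or a mapping from element class
        (``ms_promoter``, ``ms_enhancer``, ``ets``, ``none``) to a fraction.
    attenuation :
        Multiplier ``s`` applied to the endogenous log2 fold change of a
        rescued gene; ``s < 1`` means the construct drives a weaker response
        than the endogenous factor.
    paradox_frac :
        Fraction of *rescued* genes regulated in the direction opposite to
        the endogenous effect (same attenuated magnitude, flipped sign).
    """

    rescue_frac: float | dict = 0.75
    attenuation: float = 0.8
    paradox_frac: float = 0.0

    def frac_for(self, element_class: str) -> float:
        if isinstance(self.rescue_frac, dict):
            return float(self.rescue_frac.get(element_class, self.rescue_frac.get("default", 0.0)))
        return float(self.rescue_frac)

    def validate(self, name: str) -> None:
        fracs = (
            list(self.rescue_frac.values())
            if isinstance(self.rescue_frac, dict)
            else [self.rescue_frac]
        )
        for f in fracs:
            if not 0.0 <= float(f) <= 1.0:
                raise ValueError(f"rescue_frac for construct {name!r} must be in [0,1], got {f}")
        if not 0.0 <= self.attenuation <= 1.5:
            raise ValueError(f"attenuation for construct {name!r} must be in [0,1.5]")
        if not 0.0 <= self.paradox_frac <= 1.0:
            raise ValueError(f"paradox_frac for construct {name!r} must be in [0,1]")


@dataclass
class ElementConfig:
    """Layout of the synthetic genome and the planted response elements.

    Microsatellite-bearing genes each own a large block on one chromosome so
    that the nearest planted microsatellite of a gene is always its own; ETS
    genes sit on a second, microsatellite-free chromosome; all remaining
    genes are packed densely on a third chromosome with no elements at all.
    """

    n_promoter_ms: int = 120
    n_enhancer_ms: int = 120
    n_ets: int = 80
    repeat_min: int = 6          # GGAA units per planted microsatellite
    repeat_max: int = 24
    gapped_frac: float = 0.3     # fraction of microsatellites planted as two runs
    promoter_dist: tuple[int, int] = (200, 4500)   # bp, edge to TSS (< 5 kb)
    enhancer_dist: tuple[int, int] = (6000, 40000)  # bp, edge to TSS (> 5 kb)
    ms_block: int = 100_000      # bp of private territory per microsatellite gene
    ets_spacing: int = 10_000
    none_spacing: int = 600

    def validate(self) -> None:
        if min(self.n_promoter_ms, self.n_enhancer_ms, self.n_ets) < 0:
            raise ValueError("element counts must be >= 0")
        if self.repeat_min < 1 or self.repeat_max < self.repeat_min:
            raise ValueError("invalid repeat-length range")
        if self.enhancer_dist[1] + 4 * self.repeat_max + 64 > self.ms_block // 2:
            raise ValueError(
                "ms_block too small to place enhancer-like elements without overlap"
            )
        if self.ets_spacing < 12_200:  # window is [TSS-5kb, TSS+1kb] either strand
            # motifs of neighbouring genes must stay out of each other's window
            if self.ets_spacing < 6200:
                raise ValueError("ets_spacing too small for non-overlapping windows")


@dataclass
class SimConfig:
    """Full description of one simulated knockdown/rescue experiment.

    One sample per condition per batch: a batch is a replicate experiment in
    which every condition was processed together.  Defaults describe three
    replicate batches of an isogenic cell line profiled at moderate depth,
    with a wildtype rescue (``WT``), a partially active mutant (``DAF``) and
    a dead construct (``DEAD``) whose planted rescue fractions, attenuation
    slopes and paradoxical fractions follow the behaviour reported for
    wildtype, DAF-like and EWS-domain-deleted constructs.
    """

    n_genes: int = 6000
    conditions: tuple = ("iLuc", "iEF", "WT", "DAF", "DEAD")
    n_batches: int = 3
    baseline_mean_log2: tuple[float, float] = (7.5, 1.3)   # per-gene log2 baseline
    dispersion: tuple[float, float] = (float(np.log(0.005)), 0.4)  # ln-normal params
    frac_endo_activated: float = 0.15
    frac_endo_repressed: float = 0.20
    endo_lfc: tuple[float, float] = (3.5, 0.8)  # |log2 FC| of endogenous regulation
    construct_effects: dict = field(
        default_factory=lambda: {
            "WT": ConstructEffect(0.75, 0.8, 0.0),
            "DAF": ConstructEffect(0.40, 0.5, 0.30),
            "DEAD": ConstructEffect(0.02, 0.1, 0.0),
        }
    )
    batch_shift_sd: float = 0.4      # sd of additive per-batch per-gene log2 shifts
    batch_scale_shape: float = 0.25  # ln-sd of per-batch dispersion inflation
    libsize_sd: float = 0.2          # ln-sd of per-sample library scaling
    element_config: ElementConfig = field(default_factory=ElementConfig)
    seed: int = 0

    @property
    def constructs(self) -> list[str]:
        return [c for c in self.conditions if c not in ("iLuc", "iEF")]

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive; nothing to simulate")
        if "iLuc" not in self.conditions or "iEF" not in self.conditions:
            raise ValueError('conditions must include "iLuc" and "iEF"')
        for f in (self.frac_endo_activated, self.frac_endo_repressed):
            if not 0.0 <= f <= 1.0:
                raise ValueError("endo fractions must be in [0,1]")
        if self.frac_endo_activated + self.frac_endo_repressed > 1.0:
            raise ValueError("frac_endo_activated + frac_endo_repressed must be <= 1")
        for name in self.construct_effects:
            if name not in self.conditions:
                raise ValueError(
                    f"construct_effects names unknown condition {name!r}; "
                    f"conditions are {list(self.conditions)}"
                )
            self.construct_effects[name].validate(name)
        if (self.batch_shift_sd > 0 or self.batch_scale_shape > 0) and self.n_batches < 2:
            raise ValueError("n_batches must be >= 2 when batch effects are nonzero")
        self.element_config.validate()


@dataclass
class SimTruth:
    """Planted ground truth for parameter-recovery tests.

    ``table`` has one row per gene with columns ``gene``, ``endo_class``,
    ``endo_lfc``, ``element_class`` and, for each construct ``c``,
    ``rescued_<c>`` (bool), ``direction_<c>`` (``concordant`` /
    ``paradoxical`` / ``na``) and ``lfc_<c>`` (signed log2 units; zero
    whenever the gene is not rescued by ``c``).
    """

    table: pd.DataFrame
    constructs: list[str]

    def construct_lfc(self, construct: str) -> pd.Series:
        return self.table.set_index("gene")[f"lfc_{construct}"]

    def rescued(self, construct: str) -> pd.Series:
        return self.table.set_index("gene")[f"rescued_{construct}"]


# ---------------------------------------------------------------------------
# planning: everything that must agree between counts and annotation
# ---------------------------------------------------------------------------

def _streams(config: SimConfig) -> dict[str, np.random.Generator]:
    """Independent RNG streams in a documented, fixed order.

    Spawning named children from one root seed means e.g. element placement
    does not shift when only the counts stream is consumed differently.
    """
    root = np.random.SeedSequence(config.seed)
    names = ["plan", "counts", "annotation"]
    children = root.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _plan(config: SimConfig) -> pd.DataFrame:
    """Draw the per-gene truth table (shared by counts and annotation)."""
    rng = _streams(config)["plan"]
    n = config.n_genes
    genes = np.array([f"g{i:05d}" for i in range(n)])

    n_act = int(round(config.frac_endo_activated * n))
    n_rep = int(round(config.frac_endo_repressed * n))
    order = rng.permutation(n)
    endo_class = np.full(n, "null", dtype=object)
    endo_class[order[:n_act]] = "activated"
    endo_class[order[n_act:n_act + n_rep]] = "repressed"

    mag_mean, mag_sd = config.endo_lfc
    mag = np.abs(rng.normal(mag_mean, mag_sd, size=n))
    mag = np.maximum(mag, 0.25)  # keep planted effects detectable in principle
    endo_lfc = np.where(
        endo_class == "activated", mag, np.where(endo_class == "repressed", -mag, 0.0)
    )

    # element classes: planted preferentially on endogenously regulated genes
    # (the factor's bound response elements are, by design, its targets).
    ec = config.element_config
    element_class = np.full(n, "none", dtype=object)
    regulated = np.flatnonzero(endo_class != "null")
    unregulated = np.flatnonzero(endo_class == "null")
    pool = np.concatenate([rng.permutation(regulated), rng.permutation(unregulated)])
    wanted = [("ms_promoter", ec.n_promoter_ms), ("ms_enhancer", ec.n_enhancer_ms), ("ets", ec.n_ets)]
    total_wanted = sum(k for _, k in wanted)
    if total_wanted > n:
        raise ValueError("more planted elements requested than genes available")
    at = 0
    for klass, k in wanted:
        element_class[pool[at:at + k]] = klass
        at += k

    truth = pd.DataFrame(
        {
            "gene": genes,
            "endo_class": endo_class,
            "endo_lfc": endo_lfc,
            "element_class": element_class,
        }
    )

    # per-construct rescue flags: exact counts per element-class stratum
    for name in config.constructs:
        eff = config.construct_effects.get(name, ConstructEffect(0.0, 0.0, 0.0))
        rescued = np.zeros(n, dtype=bool)
        direction = np.full(n, "na", dtype=object)
        for klass in ELEMENT_CLASSES:
            stratum = np.flatnonzero((endo_class != "null") & (element_class == klass))
            k = int(round(eff.frac_for(klass) * len(stratum)))
            chosen = rng.permutation(stratum)[:k]
            rescued[chosen] = True
            n_par = int(round(eff.paradox_frac * len(chosen)))
            par = rng.permutation(chosen)[:n_par]
            direction[chosen] = "concordant"
            direction[par] = "paradoxical"
        sign = np.where(direction == "paradoxical", -1.0, 1.0)
        lfc = np.where(rescued, sign * eff.attenuation * endo_lfc, 0.0)
        truth[f"rescued_{name}"] = rescued
        truth[f"direction_{name}"] = direction
        truth[f"lfc_{name}"] = lfc

    return truth


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mean mu, Var = mu + alpha mu^2) via gamma-Poisson mixing."""
    alpha = np.broadcast_to(alpha, mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    poisson_like = alpha < 1e-8
    if poisson_like.any():
        out[poisson_like] = rng.poisson(mu[poisson_like])
    nb = ~poisson_like
    if nb.any():
        shape = 1.0 / alpha[nb]
        lam = rng.gamma(shape, alpha[nb] * mu[nb])
        out[nb] = rng.poisson(lam)
    return out


def simulate_experiment(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate a counts matrix, sample sheet and truth table.

    The per-gene, per-sample NB mean is ``L_j * 2**(b_g + x_gj + beta_gi)``
    where ``b_g`` is the log2 baseline, ``x_gj`` the condition effect implied
    by the truth table (``iEF`` carries none, ``iLuc`` the endogenous log2 FC,
    each construct its planted construct log2 FC), ``beta_gi`` the additive
    batch shift and ``L_j`` a per-sample library scaling.  Per-batch variance
    inflation multiplies the NB dispersion.

    Returns
    -------
    counts : DataFrame, genes x samples, int
    samples : DataFrame with columns ``sample``, ``condition``, ``batch``
    truth : SimTruth
    """
    config.validate()
    truth_table = _plan(config)
    rng = _streams(config)["counts"]
    n = config.n_genes

    b_mean, b_sd = config.baseline_mean_log2
    baseline = rng.normal(b_mean, b_sd, size=n)
    d_mu, d_sd = config.dispersion
    alpha_g = np.exp(rng.normal(d_mu, d_sd, size=n))

    batches = [f"b{i+1}" for i in range(config.n_batches)]
    sample_rows = [
        (f"{cond}_{b}", cond, b) for b in batches for cond in config.conditions
    ]
    samples = pd.DataFrame(sample_rows, columns=["sample", "condition", "batch"])

    # condition effect per gene: log2 offsets relative to the iEF reference
    cond_lfc = {"iEF": np.zeros(n), "iLuc": truth_table["endo_lfc"].to_numpy()}
    for c in config.constructs:
        cond_lfc[c] = truth_table[f"lfc_{c}"].to_numpy()

    batch_shift = (
        rng.normal(0.0, config.batch_shift_sd, size=(n, config.n_batches))
        if config.batch_shift_sd > 0
        else np.zeros((n, config.n_batches))
    )
    batch_scale = (
        rng.lognormal(0.0, config.batch_scale_shape, size=config.n_batches)
        if config.batch_scale_shape > 0
        else np.ones(config.n_batches)
    )
    libsize = (
        rng.lognormal(0.0, config.libsize_sd, size=len(samples))
        if config.libsize_sd > 0
        else np.ones(len(samples))
    )

    counts = np.empty((n, len(samples)), dtype=np.int64)
    for j, (_, cond, batch) in enumerate(sample_rows):
        bi = batches.index(batch)
        log2_mu = baseline + cond_lfc[cond] + batch_shift[:, bi]
        mu = libsize[j] * np.exp2(np.clip(log2_mu, -20, 30))
        counts[:, j] = _nb_draw(rng, mu, alpha_g * batch_scale[bi])

    counts_df = pd.DataFrame(counts, index=truth_table["gene"].to_numpy(),
                             columns=samples["sample"].to_numpy())
    counts_df.index.name = "gene"
    return counts_df, samples, SimTruth(truth_table, config.constructs)


# ---------------------------------------------------------------------------
# annotation / sequence
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _paste(seq: np.ndarray, pos: int, s: str) -> None:
    seq[pos:pos + len(s)] = np.frombuffer(s.encode(), dtype=np.uint8)


def _ms_sequence(rng: np.random.Generator, total: int, gapped: bool, minus: bool,
                 max_gap: int = 4) -> tuple[str, int, int]:
    """Build a planted microsatellite: one or two runs of GGAA (TTCC on minus).

    Returns (core sequence without guards, total_repeats, max_consecutive).
    Gap and guard letters are chosen so that no GGAA/TTCC unit and no
    high-affinity ETS motif can form across run or element boundaries.
    """
    unit = "TTCC" if minus else "GGAA"
    fill = "A" if minus else "T"
    if gapped and total >= 4:
        k1 = total // 2
        k2 = total - k1
        gap = int(rng.integers(1, max_gap + 1))
        core = unit * k1 + fill * gap + unit * k2
        return core, total, max(k1, k2)
    return unit * total, total, total


def _ets_instance(rng: np.random.Generator, motif: str, minus: bool) -> str:
    """One concrete instance of an IUPAC motif (reverse-complemented if minus)."""
    from .elements import IUPAC, reverse_complement

    inst = "".join(rng.choice(sorted(IUPAC[ch])) for ch in motif.upper())
    return reverse_complement(inst) if minus else inst


def _scrub(seq: np.ndarray, keep: list[tuple[int, int]], rng: np.random.Generator) -> None:
    """Destroy every GGAA/TTCC unit outside the planted footprints.

    Mutating the third base of a hit cannot create a fresh unit (shown by
    direct case analysis), but hits can overlap, so re-scan until clean.
    Because every ETS-motif instance contains a GGAA (or TTCC on the minus
    strand), this also removes all accidental ETS matches.
    """
    import re

    keep_arr = np.array(sorted(keep)) if keep else np.empty((0, 2), dtype=int)
    pat = re.compile(b"GGAA|TTCC")
    text = seq.tobytes()
    for _ in range(30):
        dirty = False
        for m in pat.finditer(text):
            s, e = m.start(), m.end()
            if keep_arr.size and ((keep_arr[:, 0] < e) & (keep_arr[:, 1] > s)).any():
                continue
            seq[s + 2] = ord("C") if text[s] == ord("G") else ord("A")
            dirty = True
        if not dirty:
            return
        text = seq.tobytes()
    raise RuntimeError("sequence scrubbing did not converge")


def simulate_annotation(config: SimConfig) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame]:
    """Emit a synthetic genome, gene TSS records, and planted elements.

    Returns
    -------
    chroms : dict chrom name -> sequence string
    genes : DataFrame(chrom, tss, strand, gene), TSS 0-based
    elements : DataFrame(chrom, start, end, strand, element_id, type,
        max_consecutive, total_repeats, fli_enrichment, gene) --- coordinates
        0-based half-open; ``gene`` is the planted target (annotation truth).

    The planted sequence content is exact: scanning the emitted FASTA with
    the response-element scanners recovers every element, and nothing else.
    """
    config.validate()
    truth = _plan(config)
    rng = _streams(config)["annotation"]
    ec = config.element_config

    ms_genes = truth.index[truth["element_class"].isin(["ms_promoter", "ms_enhancer"])].to_numpy()
    ets_genes = truth.index[truth["element_class"] == "ets"].to_numpy()
    none_genes = truth.index[truth["element_class"] == "none"].to_numpy()

    gene_rows: list[tuple] = []
    elem_rows: list[tuple] = []
    chroms: dict[str, str] = {}

    # --- chromosome of microsatellite genes: one private block per gene ----
    if len(ms_genes):
        B = ec.ms_block
        seq = _random_seq(rng, B * len(ms_genes))
        keep: list[tuple[int, int]] = []
        for i, gi in enumerate(ms_genes):
            tss = i * B + B // 2
            strand = "+" if rng.random() < 0.5 else "-"
            gene_rows.append(("chrMS", tss, strand, truth.at[gi, "gene"]))
            klass = truth.at[gi, "element_class"]
            lo, hi = ec.promoter_dist if klass == "ms_promoter" else ec.enhancer_dist
            dist = int(rng.integers(lo, hi + 1))
            total = int(rng.integers(ec.repeat_min, ec.repeat_max + 1))
            minus = rng.random() < 0.5
            core, tot, maxc = _ms_sequence(rng, total, rng.random() < ec.gapped_frac, minus)
            if rng.random() < 0.5:  # element right of the TSS: start - tss == dist
                start = tss + dist
            else:                   # element left of the TSS: tss - end == dist
                start = tss - dist - len(core)
            guard_l, guard_r = ("G", "A") if minus else ("T", "T")
            _paste(seq, start - 1, guard_l)
            _paste(seq, start, core)
            _paste(seq, start + len(core), guard_r)
            keep.append((start, start + len(core)))
            elem_rows.append(
                ("chrMS", start, start + len(core), "-" if minus else "+",
                 f"ms_{i:04d}", "ggaa_ms", maxc, tot,
                 float(np.round(rng.lognormal(2.0, 0.5), 4)), truth.at[gi, "gene"])
            )
        _scrub(seq, keep, rng)
        chroms["chrMS"] = seq.tobytes().decode()

    # --- chromosome of ETS-motif genes (no microsatellites here) -----------
    if len(ets_genes):
        S = ec.ets_spacing
        seq = _random_seq(rng, S * len(ets_genes))
        keep = []
        for i, gi in enumerate(ets_genes):
            tss = i * S + S // 2
            strand = "+" if rng.random() < 0.5 else "-"
            gene_rows.append(("chrETS", tss, strand, truth.at[gi, "gene"]))
            minus = rng.random() < 0.5
            inst = _ets_instance(rng, "ACMGGAARY", minus)
            # place inside the strand-aware direct window, clear of the edges
            if strand == "+":
                start = tss - int(rng.integers(100, 4800))
            else:
                start = tss + int(rng.integers(100, 4800))
            _paste(seq, start, inst)
            keep.append((start, start + len(inst)))
            elem_rows.append(
                ("chrETS", start, start + len(inst), "-" if minus else "+",
                 f"ets_{i:04d}", "ets_motif", 1, 1, float("nan"), truth.at[gi, "gene"])
            )
        _scrub(seq, keep, rng)
        chroms["chrETS"] = seq.tobytes().decode()

    # --- element-free chromosome for everything else ------------------------
    if len(none_genes):
        S = ec.none_spacing
        seq = _random_seq(rng, S * len(none_genes))
        for i, gi in enumerate(none_genes):
            tss = i * S + S // 2
            strand = "+" if rng.random() < 0.5 else "-"
            gene_rows.append(("chrNONE", tss, strand, truth.at[gi, "gene"]))
        _scrub(seq, [], rng)
        chroms["chrNONE"] = seq.tobytes().decode()

    genes = pd.DataFrame(gene_rows, columns=["chrom", "tss", "strand", "gene"])
    elements = pd.DataFrame(
        elem_rows,
        columns=["chrom", "start", "end", "strand", "element_id", "type",
                 "max_consecutive", "total_repeats", "fli_enrichment", "gene"],
    )
    return chroms, genes, elements
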