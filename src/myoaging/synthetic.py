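"""Synthetic cohorts, reporter-ion tables, annotations and TPM tables.

The generators emulate the statistical structure of a TMT 6-plex aging
study of skeletal muscle: donors spread evenly over five age strata
(20-34, 35-49, 50-64, 65-79, 80+), multiplexed five per batch with a
pooled reference in channel 6; protein log2 abundance drifting linearly
with age at rates of order 0.001-0.02 log2 units per year on top of
batch, sample-loading and peptide bias effects; and transcript TPM
tables in which isoform usage (PSI) shifts with age on the logistic
scale. Every generator is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import categorize_activity
from .events import ASEvent, EVENT_TYPES
from .gtf import TranscriptModel, write_gtf

__all__ = [
    "STRATA",
    "CHANNEL_COLUMNS",
    "REFERENCE_CHANNEL",
    "SimulationTruth",
    "simulate_cohort",
    "simulate_protein_truth",
    "simulate_tmt_spectra",
    "make_toy_annotation",
    "toy_gene_models",
    "random_toy_genes",
    "simulate_splicing_truth",
    "simulate_transcript_tpm",
]

#: age strata: (label, low, high) with ages drawn uniformly in [low, high)
STRATA = (
    ("20-34", 20.0, 35.0),
    ("35-49", 35.0, 50.0),
    ("50-64", 50.0, 65.0),
    ("65-79", 65.0, 80.0),
    ("80+", 80.0, 87.0),
)

#: TMT 6-plex reporter columns, channel 1..6 = label 126..131
CHANNEL_COLUMNS = tuple(f"intensity_{m}" for m in range(126, 132))
#: channel 6 (131) carries the pooled reference sample in every batch
REFERENCE_CHANNEL = 6

MYOSINS = ("MYH7", "MYH1", "MYH2", "MYH4")
#: sign of the planted age slope for each myosin: the slow isoform MYH7
#: rises with age while the fast isoforms decline, so the slow/fast
#: fiber ratio increases in older donors
_MYOSIN_SIGNS = {"MYH7": 1.0, "MYH1": -1.0, "MYH2": -1.0, "MYH4": -1.0}


@dataclass
class SimulationTruth:
    """Generative ground truth for one simulated study.

    ``proteins`` has one row per protein (baseline log2 abundance,
    beta_age in log2 units/year, n_peptides, resid_sd); ``batch_effects``
    is protein x batch; ``peptide_bias`` maps protein -> per-peptide log2
    offsets. ``events`` (optional) carries per-event PSI model parameters
    on the logit scale.
    """

    proteins: pd.DataFrame
    batch_effects: pd.DataFrame
    peptide_bias: dict[str, np.ndarray]
    seed: int
    frac_age_assoc: float
    beta_range: tuple[float, float]
    missing_rate: float | None = None
    events: pd.DataFrame | None = None

    @property
    def null_proteins(self) -> pd.Index:
        return self.proteins.index[self.proteins["beta_age"] == 0.0]


def stratum_of(age: float) -> str:
    for label, lo, hi in STRATA:
        if lo <= age < hi or (label == "80+" and age >= 80.0):
            return label
    raise ValueError(f"age {age} outside the 20-87 study range")


def simulate_cohort(n_per_stratum: int, seed: int = 0) -> pd.DataFrame:
    """Donor table for a balanced multi-batch TMT design.

    Produces ``5 * n_per_stratum`` donors, one per stratum per batch,
    with ages uniform within strata. Each TMT batch holds five donors in
    channels 1-5 (randomly assigned) and reserves channel 6 for the
    pooled reference. The study layout is ``n_per_stratum = 12``: 60
    donors in 12 six-plex batches.
    """
    if n_per_stratum < 1:
        raise ValueError("n_per_stratum must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    donor_no = 0
    for batch in range(1, n_per_stratum + 1):
        channels = rng.permutation(5) + 1
        for (label, lo, hi), channel in zip(STRATA, channels):
            donor_no += 1
            age = float(rng.uniform(lo, hi))
            minutes = float(np.round(rng.gamma(shape=1.2, scale=90.0), 1))
            rows.append(
                {
                    "donor_id": f"D{donor_no:03d}",
                    "age": round(age, 2),
                    "stratum": label,
                    "sex": rng.choice(["F", "M"]),
                    "race": rng.choice(["C", "AA", "A"], p=[0.65, 0.25, 0.10]),
                    "bmi": round(float(np.clip(rng.normal(25.0, 2.5), 19.0, 29.9)), 1),
                    "activity_minutes": minutes,
                    "activity_category": categorize_activity(minutes),
                    "tmt_batch": batch,
                    "tmt_channel": int(channel),
                }
            )
    donors = pd.DataFrame(rows).set_index("donor_id")
    # RNA-seq batches: consecutive groups of ten donors
    donors["rna_batch"] = [f"R{i // 10 + 1}" for i in range(len(donors))]
    return donors


def simulate_protein_truth(
    n_proteins: int,
    frac_age_assoc: float = 0.29,
    beta_range: tuple[float, float] = (0.001, 0.02),
    seed: int = 0,
    n_batches: int = 12,
    batch_sd: float = 0.2,
    bias_sd: float = 0.5,
    resid_sd: float = 0.2,
) -> SimulationTruth:
    """Ground-truth protein parameters.

    Exactly ``round(n_proteins * frac_age_assoc)`` proteins receive a
    nonzero age slope with magnitude uniform over ``beta_range`` and
    random sign; the rest are exactly null. The four myosin isoforms
    (MYH7, MYH1, MYH2, MYH4) are always present as the first proteins
    and, when the age-associated budget allows, take the leading nonzero
    slopes with the biologically expected signs (slow up, fast down).
    """
    if not 0.0 <= frac_age_assoc <= 1.0:
        raise ValueError("frac_age_assoc must lie in [0, 1]")
    lo, hi = beta_range
    if not (0 < lo <= hi):
        raise ValueError("beta_range must be a positive interval (lo, hi]")
    if n_proteins < len(MYOSINS):
        raise ValueError(f"need at least {len(MYOSINS)} proteins for the myosin panel")
    rng = np.random.default_rng(seed)
    names = list(MYOSINS) + [f"P{i:05d}" for i in range(1, n_proteins - len(MYOSINS) + 1)]

    n_assoc = int(round(n_proteins * frac_age_assoc))
    beta = np.zeros(n_proteins)
    n_myo = min(len(MYOSINS), n_assoc)
    for i in range(n_myo):
        beta[i] = _MYOSIN_SIGNS[names[i]] * rng.uniform(lo, hi)
    n_rest = n_assoc - n_myo
    if n_rest > 0:
        others = rng.choice(
            np.arange(len(MYOSINS), n_proteins), size=n_rest, replace=False
        )
        beta[others] = rng.uniform(lo, hi, size=n_rest) * rng.choice([-1.0, 1.0], size=n_rest)

    n_pep = rng.poisson(2.0, size=n_proteins) + 1
    proteins = pd.DataFrame(
        {
            "baseline": rng.normal(16.0, 1.5, size=n_proteins),
            "beta_age": beta,
            "n_peptides": n_pep,
            "resid_sd": np.full(n_proteins, float(resid_sd)),
        },
        index=pd.Index(names, name="protein"),
    )
    batch_effects = pd.DataFrame(
        rng.normal(0.0, batch_sd, size=(n_proteins, n_batches)) if batch_sd > 0
        else np.zeros((n_proteins, n_batches)),
        index=proteins.index,
        columns=pd.RangeIndex(1, n_batches + 1, name="tmt_batch"),
    )
    bias = {
        name: (rng.normal(0.0, bias_sd, size=k) if bias_sd > 0 else np.zeros(k))
        for name, k in zip(names, n_pep)
    }
    return SimulationTruth(
        proteins=proteins,
        batch_effects=batch_effects,
        peptide_bias=bias,
        seed=seed,
        frac_age_assoc=frac_age_assoc,
        beta_range=(lo, hi),
    )


def simulate_tmt_spectra(
    donors: pd.DataFrame,
    truth: SimulationTruth,
    noise_sd: float | None = None,
    missing_rate: float = 0.01,
    seed: int = 0,
    loading_sd: float = 0.1,
    decoy_frac: float = 0.01,
    contaminant_frac: float = 0.01,
    shared_frac: float = 0.01,
) -> pd.DataFrame:
    """Reporter-ion spectrum table for every TMT batch of the cohort.

    One spectrum per peptide per batch, with linear-scale intensities

        2 ** (baseline + beta * age + batch + loading + peptide_bias + eps),

    where eps ~ Normal(0, noise_sd) (``noise_sd=None`` uses each
    protein's own residual sd from the truth). The reference channel
    carries a pooled pseudo-donor at the cohort mean age. Missing values
    are injected completely at random at ``missing_rate`` per cell; a
    small fraction of decoy/contaminant/shared-flagged spectra is added
    to exercise the QC filters.
    """
    if not 0.0 <= missing_rate <= 1.0:
        raise ValueError("missing_rate must lie in [0, 1]")
    batches = np.sort(donors["tmt_batch"].unique())
    for b in batches:
        sub = donors[donors["tmt_batch"] == b]
        if sorted(sub["tmt_channel"]) != [1, 2, 3, 4, 5]:
            raise ValueError(f"batch {b} must cover channels 1-5 exactly once")
    rng = np.random.default_rng(seed)
    ref_age = float(donors["age"].mean())

    prot = truth.proteins
    n_pep = prot["n_peptides"].to_numpy()
    S = int(n_pep.sum())  # spectra per batch
    protein_rep = np.repeat(prot.index.to_numpy(), n_pep)
    baseline_rep = np.repeat(prot["baseline"].to_numpy(), n_pep)
    beta_rep = np.repeat(prot["beta_age"].to_numpy(), n_pep)
    sd_rep = (
        np.full(S, float(noise_sd))
        if noise_sd is not None
        else np.repeat(prot["resid_sd"].to_numpy(), n_pep)
    )
    bias_rep = np.concatenate([truth.peptide_bias[p] for p in prot.index])
    pep_idx = np.concatenate([np.arange(k) + 1 for k in n_pep])
    peptide_rep = np.array([f"{p}_pep{j}" for p, j in zip(protein_rep, pep_idx)])

    frames = []
    for b in batches:
        sub = donors[donors["tmt_batch"] == b]
        ages = np.empty(6)
        ages[5] = ref_age
        for ch, age in zip(sub["tmt_channel"], sub["age"]):
            ages[ch - 1] = age
        loading = rng.normal(0.0, loading_sd, size=6) if loading_sd > 0 else np.zeros(6)
        batch_fx = np.repeat(truth.batch_effects[b].to_numpy(), n_pep)
        log2 = (
            baseline_rep[:, None]
            + beta_rep[:, None] * ages[None, :]
            + batch_fx[:, None]
            + loading[None, :]
            + bias_rep[:, None]
        )
        if np.any(sd_rep > 0):
            log2 = log2 + rng.normal(0.0, 1.0, size=(S, 6)) * sd_rep[:, None]
        inten = np.exp2(log2)
        if missing_rate > 0:
            inten[rng.random((S, 6)) < missing_rate] = np.nan
        df = pd.DataFrame(inten, columns=list(CHANNEL_COLUMNS))
        df.insert(0, "spectrum_id", [f"B{b:02d}_S{i:05d}" for i in range(S)])
        df.insert(1, "peptide", peptide_rep)
        df.insert(2, "protein", protein_rep)
        df.insert(3, "batch", b)
        df["decoy"] = False
        df["contaminant"] = False
        df["shared"] = False
        frames.append(df)
        frames.extend(
            _flagged_spectra(rng, b, S, prot.index, decoy_frac, contaminant_frac, shared_frac)
        )
    out = pd.concat(frames, ignore_index=True)
    return out


def _flagged_spectra(rng, batch, S, protein_index, decoy_frac, contaminant_frac, shared_frac):
    """QC-flagged junk spectra (decoy/contaminant/shared) for one batch."""
    frames = []
    specs = [
        ("decoy", decoy_frac, lambda i: f"DECOY_{i}"),
        ("contaminant", contaminant_frac, lambda i: f"CONT_{i}"),
        ("shared", shared_frac, lambda i: rng.choice(protein_index)),
    ]
    for flag, frac, namer in specs:
        k = int(round(frac * S))
        if k == 0:
            continue
        inten = np.exp2(rng.normal(14.0, 2.0, size=(k, 6)))
        df = pd.DataFrame(inten, columns=list(CHANNEL_COLUMNS))
        df.insert(0, "spectrum_id", [f"B{batch:02d}_{flag[:3].upper()}{i:04d}" for i in range(k)])
        df.insert(1, "peptide", [f"{flag}_pep{i}" for i in range(k)])
        df.insert(2, "protein", [str(namer(i)) for i in range(k)])
        df.insert(3, "batch", batch)
        df["decoy"] = flag == "decoy"
        df["contaminant"] = flag == "contaminant"
        df["shared"] = flag == "shared"
        frames.append(df)
    return frames


# ---------------------------------------------------------------------------
# splicing fixtures
# ---------------------------------------------------------------------------

_GENE_SPACING = 1000


def _plant_gene(etype: str, strand: str, gene: str, chrom: str, o: int):
    """Two-transcript gene with exactly one planted event of ``etype``."""
    t1, t2 = f"{gene}.t1", f"{gene}.t2"

    def T(tid, exons):
        return TranscriptModel(gene, tid, chrom, strand, tuple(exons))

    inc1 = frozenset({t1})
    inc2 = frozenset({t2})
    both = frozenset({t1, t2})
    if etype == "SE":
        models = [
            T(t1, [(o, o + 100), (o + 200, o + 300), (o + 400, o + 500)]),
            T(t2, [(o, o + 100), (o + 400, o + 500)]),
        ]
        ev = ASEvent("SE", gene, chrom, strand,
                     (o + 100, o + 200, o + 300, o + 400), inc1, both)
    elif etype == "RI":
        models = [
            T(t1, [(o, o + 100), (o + 200, o + 300)]),
            T(t2, [(o, o + 300)]),
        ]
        ev = ASEvent("RI", gene, chrom, strand,
                     (o, o + 100, o + 200, o + 300), inc2, both)
    elif (etype, strand) in (("A3", "+"), ("A5", "-")):
        # introns share their genomic start, differ at the end
        models = [
            T(t1, [(o, o + 100), (o + 200, o + 300)]),
            T(t2, [(o, o + 100), (o + 240, o + 300)]),
        ]
        ev = ASEvent(etype, gene, chrom, strand,
                     (o + 100, o + 200, o + 100, o + 240), inc1, both)
    elif (etype, strand) in (("A5", "+"), ("A3", "-")):
        # introns share their genomic end, differ at the start
        models = [
            T(t1, [(o, o + 100), (o + 200, o + 300)]),
            T(t2, [(o, o + 140), (o + 200, o + 300)]),
        ]
        ev = ASEvent(etype, gene, chrom, strand,
                     (o + 140, o + 200, o + 100, o + 200), inc2, both)
    elif etype == "MX":
        models = [
            T(t1, [(o, o + 100), (o + 150, o + 200), (o + 350, o + 450)]),
            T(t2, [(o, o + 100), (o + 250, o + 300), (o + 350, o + 450)]),
        ]
        ev = ASEvent("MX", gene, chrom, strand,
                     (o + 100, o + 150, o + 200, o + 250, o + 300, o + 350),
                     inc1, both)
    elif (etype, strand) in (("AF", "+"), ("AL", "-")):
        # variable exons at the genomic left end, shared second-exon start
        models = [
            T(t1, [(o, o + 80), (o + 300, o + 400)]),
            T(t2, [(o + 120, o + 200), (o + 300, o + 400)]),
        ]
        ev = ASEvent(etype, gene, chrom, strand,
                     (o, o + 80, o + 120, o + 200, o + 300), inc1, both,
                     left_variant=True)
    elif (etype, strand) in (("AL", "+"), ("AF", "-")):
        # variable exons at the genomic right end, shared first-exon end
        models = [
            T(t1, [(o, o + 100), (o + 300, o + 380)]),
            T(t2, [(o, o + 100), (o + 420, o + 500)]),
        ]
        ev = ASEvent(etype, gene, chrom, strand,
                     (o + 100, o + 420, o + 500, o + 300, o + 380), inc2, both,
                     left_variant=False)
    else:  # pragma: no cover
        raise ValueError(f"no template for {etype} on {strand}")
    return models, ev


def toy_gene_models(
    n_copies: int = 1, gene_ids: list[str] | None = None
) -> tuple[list[TranscriptModel], list[ASEvent]]:
    """Planted two-transcript genes: one event of each of the 7 classes on
    each strand, tiled ``n_copies`` times at shifted coordinates.

    ``gene_ids`` optionally renames the genes (length ``14 * n_copies``),
    e.g. to share a symbol namespace with simulated proteins.
    """
    models, events = [], []
    idx = 0
    for copy in range(n_copies):
        for etype in EVENT_TYPES:
            for strand in ("+", "-"):
                default = f"G_{etype}_{'p' if strand == '+' else 'm'}_{copy + 1}"
                gene = gene_ids[idx] if gene_ids is not None else default
                o = idx * _GENE_SPACING
                m, ev = _plant_gene(etype, strand, gene, "chr1", o)
                models.extend(m)
                events.append(ev)
                idx += 1
    return models, events


def make_toy_annotation(
    seed: int = 0, n_copies: int = 1, gene_ids: list[str] | None = None
) -> tuple[str, list[ASEvent]]:
    """GTF text plus the ground-truth event list for the planted genes.

    The layout is deterministic; ``seed`` is accepted for interface
    symmetry with the other generators.
    """
    del seed
    models, events = toy_gene_models(n_copies=n_copies, gene_ids=gene_ids)
    return write_gtf(models), events


def random_toy_genes(n_genes: int, seed: int = 0) -> list[list[TranscriptModel]]:
    """Random multi-transcript toy genes for oracle-equivalence testing.

    Each gene starts from a base transcript of 4-6 exons; 1-3 variant
    transcripts are derived by randomly skipping an exon, retaining an
    intron, shifting a donor or acceptor, substituting a mutually
    exclusive exon, or replacing the first/last exon.
    """
    rng = np.random.default_rng(seed)
    genes = []
    for g in range(n_genes):
        strand = rng.choice(["+", "-"])
        gene = f"RG{g:03d}"
        n_ex = int(rng.integers(4, 7))
        pos = 10_000 * g + 500
        exons = []
        for _ in range(n_ex):
            length = int(rng.integers(60, 160))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(250, 400))
        base = tuple(exons)
        variants = [base]
        for _ in range(int(rng.integers(1, 4))):
            variants.append(_mutate_transcript(rng, base))
        # dedup identical structures
        seen, models = set(), []
        for i, ex in enumerate(variants):
            if ex in seen:
                continue
            seen.add(ex)
            models.append(
                TranscriptModel(gene, f"{gene}.t{len(models) + 1}", "chr1", strand, ex)
            )
        genes.append(models)
    return genes


def _mutate_transcript(rng, exons: tuple[tuple[int, int], ...]) -> tuple:
    ex = [list(e) for e in exons]
    n = len(ex)
    op = rng.choice(["skip", "retain", "donor", "acceptor", "mx", "first", "last"])
    if op == "skip" and n >= 3:
        del ex[int(rng.integers(1, n - 1))]
    elif op == "retain" and n >= 2:
        i = int(rng.integers(0, n - 1))
        ex[i][1] = ex[i + 1][1]
        del ex[i + 1]
    elif op == "donor" and n >= 2:
        i = int(rng.integers(0, n - 1))
        ex[i][1] += int(rng.integers(10, 50)) * rng.choice([-1, 1])
        ex[i][1] = max(ex[i][0] + 10, min(ex[i][1], ex[i + 1][0] - 10))
    elif op == "acceptor" and n >= 2:
        i = int(rng.integers(1, n))
        ex[i][0] += int(rng.integers(10, 50)) * rng.choice([-1, 1])
        ex[i][0] = max(ex[i - 1][1] + 10, min(ex[i][0], ex[i][1] - 10))
    elif op == "mx" and n >= 3:
        i = int(rng.integers(1, n - 1))
        lo, hi = ex[i - 1][1] + 10, ex[i + 1][0] - 10
        length = int(rng.integers(40, 80))
        for _ in range(10):
            s = int(rng.integers(lo, hi - length))
            if s + length <= ex[i][0] or s >= ex[i][1]:  # no overlap with original
                ex[i] = [s, s + length]
                break
    elif op == "first":
        width = ex[0][1] - ex[0][0]
        shift = width + int(rng.integers(30, 120))
        ex[0] = [ex[0][0] - shift, ex[0][1] - shift]
    elif op == "last":
        width = ex[-1][1] - ex[-1][0]
        shift = width + int(rng.integers(30, 120))
        ex[-1] = [ex[-1][0] + shift, ex[-1][1] + shift]
    return tuple(tuple(e) for e in ex)


def simulate_splicing_truth(
    events: list[ASEvent],
    frac_age_assoc: float = 0.5,
    slope_range: tuple[float, float] = (0.004, 0.012),
    seed: int = 0,
    center_age: float = 53.0,
) -> pd.DataFrame:
    """Per-event PSI model parameters on the logit scale.

    A fraction of events receives a nonzero logit-scale age slope with
    magnitude uniform over ``slope_range`` (at PSI near 0.5 a logit
    slope of 0.008/year corresponds to ~0.002 PSI/year, the scale of
    age-associated splicing shifts); intercepts center the expected PSI
    near 0.5 at ``center_age``, which keeps it inside (0, 1) at every
    age. Null events sit at a random constant PSI in (0.2, 0.8).
    """
    rng = np.random.default_rng(seed)
    n = len(events)
    n_assoc = int(round(n * frac_age_assoc))
    nonzero = rng.choice(n, size=n_assoc, replace=False)
    slope = np.zeros(n)
    slope[nonzero] = rng.uniform(*slope_range, size=n_assoc) * rng.choice(
        [-1.0, 1.0], size=n_assoc
    )
    base_psi = rng.uniform(0.2, 0.8, size=n)
    intercept = np.where(
        slope != 0.0, -slope * center_age, np.log(base_psi / (1 - base_psi))
    )
    return pd.DataFrame(
        {
            "event_id": [ev.event_id for ev in events],
            "gene_id": [ev.gene_id for ev in events],
            "inclusion_transcript": [sorted(ev.inclusion_transcripts)[0] for ev in events],
            "psi_intercept": intercept,
            "psi_slope": slope,
        }
    ).set_index("event_id")


def simulate_transcript_tpm(
    donors: pd.DataFrame,
    models: list[TranscriptModel],
    truth: pd.DataFrame,
    dispersion: float = 0.1,
    seed: int = 0,
    total_tpm: float = 1e6,
) -> tuple[pd.DataFrame, int]:
    """Transcript x donor TPM table with age-dependent isoform switching.

    Gene-level expression is log-normal; within genes that carry a PSI
    truth entry the inclusion isoform's expected share follows
    ``logistic(psi_intercept + psi_slope * age)``, other genes split
    evenly. Multiplicative log-normal noise with the given dispersion is
    applied per transcript and donor, and each donor column is rescaled
    to sum to ``total_tpm``. Returns the table and the count of expected
    shares clipped to (0, 1) for numerical safety.
    """
    rng = np.random.default_rng(seed)
    ages = donors["age"].to_numpy(dtype=float)
    n_d = len(ages)
    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    gene_truth = truth.reset_index().set_index("gene_id") if len(truth) else truth

    tids, blocks = [], []
    n_clipped = 0
    eps = 1e-9
    for gene in sorted(by_gene):
        trans = sorted(by_gene[gene], key=lambda m: m.transcript_id)
        expr = np.exp(rng.normal(np.log(100.0), 0.5, size=n_d))
        k = len(trans)
        if len(truth) and gene in gene_truth.index:
            row = gene_truth.loc[gene]
            if isinstance(row, pd.DataFrame):  # several events per gene: use first
                row = row.iloc[0]
            p = 1.0 / (1.0 + np.exp(-(row["psi_intercept"] + row["psi_slope"] * ages)))
            clipped = (p < eps) | (p > 1 - eps)
            n_clipped += int(clipped.sum())
            p = np.clip(p, eps, 1 - eps)
            inc_tid = row["inclusion_transcript"]
            shares = np.array(
                [p if m.transcript_id == inc_tid else (1.0 - p) / max(k - 1, 1)
                 for m in trans]
            )
        else:
            shares = np.full((k, n_d), 1.0 / k)
        noise = (
            np.exp(rng.normal(0.0, dispersion, size=(k, n_d)))
            if dispersion > 0
            else np.ones((k, n_d))
        )
        blocks.append(expr[None, :] * shares * noise)
        tids.extend(m.transcript_id for m in trans)
    tpm = np.vstack(blocks)
    tpm *= total_tpm / tpm.sum(axis=0, keepdims=True)
    table = pd.DataFrame(tpm, index=pd.Index(tids, name="transcript_id"),
                         columns=donors.index)
    return table, n_clipped
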