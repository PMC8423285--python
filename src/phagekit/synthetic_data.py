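"""Synthetic inputs with known ground truth for every pipeline stage.

Generators emulate the data shapes of a phage characterization study:
coding genome pairs with controlled per-amino-acid codon bias (for the
codon-usage analysis), one-step growth curves with latent/rise/plateau
structure, Poisson plaque counts over a dilution series, and two-group
biofilm datasets with preset effect sizes.

Every generator is a pure function of its spec + seed: fixed seed gives
bit-identical output.  Each call builds its own ``numpy.random.default_rng``
stream; no global state is touched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .biofilm_stats import TwoGroupData
from .codon_usage import CODON_TO_AA, CODONS
from .growth_kinetics import GrowthCurve
from .plating import DEFAULT_SPOT_VOLUME_ML, SpotSeries
from .sequence_io import CdsFeature, GenomeRecord, reverse_complement

# synonymous families of the standard code (stops under "*")
AA_FAMILIES: dict[str, tuple[str, ...]] = {}
for _c in CODONS:
    AA_FAMILIES.setdefault(CODON_TO_AA[_c], tuple())
    AA_FAMILIES[CODON_TO_AA[_c]] += (_c,)

AMINO_ACIDS: tuple[str, ...] = tuple(sorted(a for a in AA_FAMILIES if a != "*"))
STOPS: tuple[str, ...] = AA_FAMILIES["*"]


def _uniform_weights() -> dict[str, dict[str, float]]:
    return {
        aa: {c: 1.0 / len(codons) for c in codons}
        for aa, codons in AA_FAMILIES.items()
    }


@dataclass
class CodonBiasSpec:
    """Generating distribution for one organism's coding sequences.

    ``codon_weights`` maps each amino acid (one-letter, "*" for stop) to a
    normalized weight vector over its synonymous codons.  Body amino acids
    are drawn from ``aa_freqs`` (uniform over the 20 by default); each gene
    is ATG + body codons + one stop codon.
    """

    n_genes: int = 60
    length_min: int = 100  # codons, uniform inclusive
    length_max: int = 400
    seed: int = 0
    codon_weights: dict[str, dict[str, float]] = field(default_factory=_uniform_weights)
    aa_freqs: dict[str, float] = field(
        default_factory=lambda: {aa: 1.0 / len(AMINO_ACIDS) for aa in AMINO_ACIDS}
    )

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not (2 <= self.length_min <= self.length_max):
            raise ValueError("need 2 <= length_min <= length_max")
        for aa, w in self.codon_weights.items():
            total = sum(w.values())
            if total <= 0:
                raise ValueError(f"weight vector for {aa!r} sums to zero")
            self.codon_weights[aa] = {c: v / total for c, v in w.items()}

    def boosted(self, codon: str, factor: float) -> "CodonBiasSpec":
        """Copy with one codon's weight multiplied by ``factor`` within its
        synonymous family, the rest scaled down to keep the family sum 1."""
        aa = CODON_TO_AA[codon]
        w = dict(self.codon_weights[aa])
        new = w[codon] * factor
        if new >= 1.0:
            raise ValueError(f"boost factor {factor} pushes {codon} weight to {new} >= 1")
        rest = 1.0 - w[codon]
        scale = (1.0 - new) / rest
        boosted = {c: (new if c == codon else v * scale) for c, v in w.items()}
        weights = {a: dict(v) for a, v in self.codon_weights.items()}
        weights[aa] = boosted
        return replace(self, codon_weights=weights)

    def body_codon_probs(self) -> dict[str, float]:
        """Marginal codon distribution of a body (non-start, non-stop) position."""
        p = {c: 0.0 for c in CODONS}
        for aa in AMINO_ACIDS:
            fa = self.aa_freqs[aa]
            for c, w in self.codon_weights[aa].items():
                p[c] += fa * w
        return p


@dataclass
class GenomeHalf:
    """One organism of a generated pair: sequence, features, truth table."""

    record: GenomeRecord
    features: list[CdsFeature]
    true_f: dict[str, float]


@dataclass
class GenomePair:
    host: GenomeHalf
    phage: GenomeHalf
    true_r: dict[str, float | None]

    def write_fixtures(self, out_dir: str | Path, manifest: dict | None = None) -> dict[str, str]:
        """Write FASTA/GFF3 for both organisms plus a manifest JSON."""
        from .sequence_io import write_fasta

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, half in (("host", self.host), ("phage", self.phage)):
            fasta = out_dir / f"{name}.fasta"
            gff = out_dir / f"{name}.gff3"
            write_fasta([half.record], fasta)
            _write_gff(half.record, half.features, gff)
            paths[f"{name}_fasta"] = str(fasta)
            paths[f"{name}_gff"] = str(gff)
        meta = {"files": paths, "true_r": self.true_r}
        if manifest:
            meta.update(manifest)
        mpath = out_dir / "manifest.json"
        with open(mpath, "w") as fh:
            json.dump(meta, fh, indent=2, default=str)
        paths["manifest"] = str(mpath)
        return paths


def _write_gff(record: GenomeRecord, features: list[CdsFeature], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {record.id} 1 {record.length}\n")
        for f in features:
            fh.write(
                f"{f.seq_id}\tphagekit\tCDS\t{f.start}\t{f.end}\t.\t{f.strand}\t{f.phase}\t"
                f"ID={f.feature_id}\n"
            )


def _draw_genes(spec: CodonBiasSpec, rng: np.random.Generator) -> list[str]:
    """Draw all genes at once (vectorized per amino-acid family)."""
    lengths = rng.integers(spec.length_min, spec.length_max + 1, size=spec.n_genes)
    total_body = int(lengths.sum())
    aa_probs = np.array([spec.aa_freqs[a] for a in AMINO_ACIDS])
    aa_idx = rng.choice(len(AMINO_ACIDS), size=total_body, p=aa_probs)
    body = np.empty(total_body, dtype="U3")
    for ai, aa in enumerate(AMINO_ACIDS):
        mask = aa_idx == ai
        n = int(mask.sum())
        if n == 0:
            continue
        fam = AA_FAMILIES[aa]
        w = np.array([spec.codon_weights[aa][c] for c in fam])
        body[mask] = rng.choice(fam, size=n, p=w)
    stop_w = np.array([spec.codon_weights["*"][c] for c in STOPS])
    stops = rng.choice(STOPS, size=spec.n_genes, p=stop_w)
    genes = []
    offset = 0
    for L, stop in zip(lengths, stops):
        genes.append("ATG" + "".join(body[offset : offset + L]) + stop)
        offset += L
    return genes


def _generate_one(spec: CodonBiasSpec, genome_id: str, spacer_len: int = 20) -> GenomeHalf:
    rng = np.random.default_rng(spec.seed)
    genes = _draw_genes(spec, rng)
    chunks: list[str] = []
    features: list[CdsFeature] = []
    pos = 0  # 0-based running offset
    for i, gene in enumerate(genes):
        spacer = "".join(rng.choice(list("ACGT"), size=spacer_len))
        chunks.append(spacer)
        pos += spacer_len
        strand = "+" if i % 2 == 0 else "-"
        placed = gene if strand == "+" else reverse_complement(gene)
        chunks.append(placed)
        features.append(
            CdsFeature(
                seq_id=genome_id,
                start=pos + 1,
                end=pos + len(gene),
                strand=strand,
                feature_id=f"{genome_id}_gene{i + 1:03d}",
            )
        )
        pos += len(gene)
    chunks.append("".join(rng.choice(list("ACGT"), size=spacer_len)))
    sequence = "".join(chunks)

    # truth table for counted codons: per gene the start is stripped, the
    # stop retained, so counted = body codons + one stop per gene
    n_body = sum(len(g) // 3 - 2 for g in genes)
    n_total = n_body + spec.n_genes
    p_body = spec.body_codon_probs()
    stop_w = spec.codon_weights["*"]
    true_f = {
        c: (n_body * p_body[c] + spec.n_genes * stop_w.get(c, 0.0)) / n_total
        for c in CODONS
    }
    return GenomeHalf(
        record=GenomeRecord(id=genome_id, sequence=sequence),
        features=features,
        true_f=true_f,
    )


def generate_genome_pair(
    host_bias: CodonBiasSpec, phage_bias: CodonBiasSpec
) -> GenomePair:
    """Generate a host/phage genome pair with known codon-usage truth.

    Each gene is ATG + codons drawn per spec + a stop codon, placed on
    alternating strands with random spacers.  The returned truth tables give
    the generating relative frequencies (start codons excluded, stops
    included, conditioned on the realized codon totals) and their ratio.
    """
    host = _generate_one(host_bias, "host")
    phage = _generate_one(phage_bias, "phage")
    true_r = {
        c: (phage.true_f[c] / host.true_f[c] if host.true_f[c] > 0 else None)
        for c in CODONS
    }
    return GenomePair(host=host, phage=phage, true_r=true_r)


# codon-usage conditions emulating a phage that over-uses a handful of codons
# relative to its host: one threonine codon over three-fold, four codons in
# other families just under three-fold
STUDY_CODON_BOOSTS: dict[str, float] = {
    "ACT": 3.1,
    "GGT": 2.8,
    "CCG": 2.8,
    "GCA": 2.8,
    "TCT": 2.8,
}


def study_like_genome_pair(
    seed: int = 0,
    n_genes: int = 150,
    length_min: int = 150,
    length_max: int = 450,
) -> GenomePair:
    """Host with uniform synonymous usage vs a phage over-using five codons.

    Emulates a phage/host pair in which one threonine codon is used more
    than three times as often by the phage (relative frequency), and four
    further codons close to three-fold, against a host with unbiased
    synonymous usage.
    """
    host = CodonBiasSpec(seed=seed, n_genes=n_genes, length_min=length_min, length_max=length_max)
    phage = CodonBiasSpec(
        seed=seed + 1, n_genes=n_genes, length_min=length_min, length_max=length_max
    )
    for codon, factor in STUDY_CODON_BOOSTS.items():
        phage = phage.boosted(codon, factor)
    return generate_genome_pair(host, phage)


@dataclass
class GrowthSimSpec:
    """Template for simulated one-step growth curves.

    The deterministic template is baseline titer until the latent period
    ends, a log-linear rise over ``rise_min`` up to baseline x burst, then a
    plateau; each sampled point gets multiplicative log-normal noise of
    ``noise_sigma_log10`` decades.
    """

    latent_min: float = 20.0
    rise_min: float = 30.0
    burst: float = 12.0
    baseline_titer: float = 1e4
    sample_interval: float = 10.0
    noise_sigma_log10: float = 0.02
    n_replicates: int = 3
    horizon_min: float | None = None  # default latent + rise + 3 intervals
    seed: int = 0

    def __post_init__(self):
        for name in ("latent_min", "rise_min", "burst", "baseline_titer", "sample_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.horizon_min is None:
            self.horizon_min = self.latent_min + self.rise_min + 3 * self.sample_interval
        if self.horizon_min < self.latent_min + self.rise_min:
            raise ValueError("horizon shorter than latent + rise")


def growth_template(spec: GrowthSimSpec, t: np.ndarray) -> np.ndarray:
    """Noise-free titer at times t under the piecewise log-linear model."""
    t = np.asarray(t, dtype=float)
    frac = np.clip((t - spec.latent_min) / spec.rise_min, 0.0, 1.0)
    return spec.baseline_titer * spec.burst**frac


def generate_growth_curves(spec: GrowthSimSpec) -> list[GrowthCurve]:
    """Simulate replicate one-step growth curves on the sampling grid."""
    rng = np.random.default_rng(spec.seed)
    times = np.arange(0.0, spec.horizon_min + spec.sample_interval / 2, spec.sample_interval)
    template = growth_template(spec, times)
    curves = []
    for i in range(spec.n_replicates):
        noise = rng.normal(0.0, spec.noise_sigma_log10, size=len(times))
        titers = template * 10**noise
        curves.append(GrowthCurve(times=times.copy(), titers=titers, replicate_id=f"rep{i + 1}"))
    return curves


def generate_spot_series(
    true_titer: float,
    exponents: list[int],
    seed: int = 0,
    spot_volume: float = DEFAULT_SPOT_VOLUME_ML,
) -> SpotSeries:
    """Poisson plaque counts over a 10-fold dilution series.

    Expected count at exponent e is true_titer * spot_volume * 10^-e.
    """
    if true_titer <= 0:
        raise ValueError("true titer must be positive")
    rng = np.random.default_rng(seed)
    counts = [
        int(rng.poisson(true_titer * spot_volume * 10.0 ** (-e))) for e in exponents
    ]
    return SpotSeries(dilution_exponents=list(exponents), plaque_counts=counts, spot_volume=spot_volume)


BIOFILM_BASELINES = {"absorbance": 1.0, "counts": 200.0}
EFFECT_PRESETS = {"none": 0.0, "strong_reduction": 0.60}  # relative mean decrease
BIOFILM_CV = 0.10  # normal noise, coefficient of variation
BIOFILM_SIGMA_LN = 0.5  # lognormal noise, sigma of ln


def generate_biofilm_data(
    n: int = 42,
    effect: str = "strong_reduction",
    noise: str = "normal",
    seed: int = 0,
    kind: str = "counts",
) -> TwoGroupData:
    """Two-group biofilm dataset with a preset treatment effect.

    ``kind`` sets the measurement scale and the pairing convention:
    "absorbance" (crystal-violet AU, paired wells) or "counts" (viable cells
    per confocal field, independent groups; the default n = 42 mirrors
    14 fields x 3 replicate experiments).  The treated group mean is reduced
    by the effect preset (none: 0%, strong_reduction: 60%).  Noise is
    normal (CV 10%) or right-skewed lognormal (sigma_ln 0.5).
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    if effect not in EFFECT_PRESETS:
        raise ValueError(f"unknown effect preset {effect!r}; choose from {sorted(EFFECT_PRESETS)}")
    if noise not in ("normal", "lognormal"):
        raise ValueError(f"unknown noise model {noise!r}")
    if kind not in BIOFILM_BASELINES:
        raise ValueError(f"unknown kind {kind!r}; choose from {sorted(BIOFILM_BASELINES)}")
    rng = np.random.default_rng(seed)
    base = BIOFILM_BASELINES[kind]
    means = (base, base * (1.0 - EFFECT_PRESETS[effect]))
    groups = []
    for mu in means:
        if noise == "normal":
            x = rng.normal(mu, BIOFILM_CV * mu, size=n)
            x = np.clip(x, mu * 1e-6, None)  # measurements are positive
        else:
            # lognormal with the requested mean: E = exp(m + s^2/2)
            m = np.log(mu) - BIOFILM_SIGMA_LN**2 / 2
            x = rng.lognormal(m, BIOFILM_SIGMA_LN, size=n)
        groups.append(x)
    return TwoGroupData(
        group_a=groups[0],
        group_b=groups[1],
        paired=(kind == "absorbance"),
        labels=("control", "treated"),
    )
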