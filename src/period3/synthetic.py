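"""Seeded synthetic DNA with codon-position nucleotide bias.

Coding DNA shows excess spectral power at 1/3 cycles/base because base
usage differs across the three codon positions.  The generator emulates
exactly that mechanism: background positions are i.i.d. uniform over
{a, c, g, t}; inside annotated exons, position ``i`` (phase anchored at
the exon start) is drawn from the mixture

    (1 - beta) * uniform  +  beta * codon_profile[i mod 3]

so ``beta = 0`` is indistinguishable from background and ``beta = 1`` is a
deterministic-profile codon pattern.  Everything is driven by an explicit
seed; identical specs give byte-identical output.

It deliberately does NOT model splice-site motifs, GC content, intron
length distributions, or reading-frame consistency between exons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .metrics import ExonAnnotation, write_bed
from .sequences import ComplexSignal, NucleotideSequence, write_fasta
from .subspace import ExponentialsInNoiseModel

__all__ = [
    "SyntheticGeneSpec",
    "DEFAULT_CODON_PROFILE",
    "generate_gene",
    "default_fixture_suite",
    "simulate_exponentials",
]

_BASES = np.array(list("acgt"))

#: Default per-codon-position base probabilities (rows: codon positions
#: 1..3; columns: a, c, g, t).  Position 1 skews toward g/a and position 3
#: toward g/c, loosely imitating the nonuniform codon-position composition
#: of real coding sequence; the exact numbers are package constants, not
#: biological claims.
DEFAULT_CODON_PROFILE = np.array(
    [
        [0.30, 0.05, 0.55, 0.10],
        [0.25, 0.20, 0.10, 0.45],
        [0.05, 0.45, 0.45, 0.05],
    ]
)

#: Deterministic codon pattern for the short-exon stress fixture: point
#: masses on (g, t, c), whose mapped values (+1, +j, -j) carry the largest
#: period-3 Fourier component any base triplet can achieve.
POINT_MASS_GTC_PROFILE = np.array(
    [
        [0.0, 0.0, 1.0, 0.0],
        [0.0, 0.0, 0.0, 1.0],
        [0.0, 1.0, 0.0, 0.0],
    ]
)


@dataclass(frozen=True)
class SyntheticGeneSpec:
    """Specification of one synthetic gene-like sequence."""

    total_length: int
    exons: tuple[tuple[int, int], ...]  # 1-based inclusive
    bias_strength: float = 0.9
    codon_profile: np.ndarray = field(default_factory=lambda: DEFAULT_CODON_PROFILE.copy())
    seed: int = 0
    name: str = "synthetic"

    def __post_init__(self) -> None:
        if self.total_length < 1:
            raise ValueError("total_length must be positive")
        if not 0.0 <= self.bias_strength <= 1.0:
            raise ValueError("bias_strength must be in [0, 1]")
        prev_end = 0
        for start, end in self.exons:
            if not (1 <= start <= end <= self.total_length):
                raise ValueError(f"exon ({start}, {end}) outside [1, {self.total_length}]")
            if start <= prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = end
        profile = np.asarray(self.codon_profile, dtype=float)
        if profile.shape != (3, 4):
            raise ValueError("codon_profile must be 3 x 4 (positions x bases a,c,g,t)")
        if np.any(profile < 0) or np.max(np.abs(profile.sum(axis=1) - 1)) > 1e-12:
            raise ValueError("each codon_profile row must be a probability vector")
        object.__setattr__(self, "codon_profile", profile)

    def to_jsonable(self) -> dict:
        return {
            "total_length": self.total_length,
            "exons": [list(e) for e in self.exons],
            "bias_strength": self.bias_strength,
            "codon_profile": self.codon_profile.tolist(),
            "seed": self.seed,
            "name": self.name,
        }

    @classmethod
    def from_jsonable(cls, d: dict) -> "SyntheticGeneSpec":
        return cls(
            total_length=d["total_length"],
            exons=tuple(tuple(e) for e in d["exons"]),
            bias_strength=d["bias_strength"],
            codon_profile=np.asarray(d["codon_profile"]),
            seed=d["seed"],
            name=d.get("name", "synthetic"),
        )


def generate_gene(spec: SyntheticGeneSpec) -> tuple[NucleotideSequence, ExonAnnotation]:
    """Draw one sequence (and its exon annotation) from the spec.

    Deterministic for a fixed spec: the same seed always yields the same
    bases.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.total_length
    beta = spec.bias_strength
    probs = np.full((L, 4), 0.25)
    for start, end in spec.exons:
        idx = np.arange(start - 1, end)  # 0-based
        phase = (idx - (start - 1)) % 3
        probs[idx] = (1 - beta) * 0.25 + beta * spec.codon_profile[phase]
    u = rng.random(L)
    cum = np.cumsum(probs, axis=1)
    choice = (u[:, None] > cum).sum(axis=1)
    bases = "".join(_BASES[choice])
    seq = NucleotideSequence(id=spec.name, bases=bases)
    ann = ExonAnnotation(intervals=spec.exons, source_id=spec.name)
    return seq, ann


#: The canonical test fixtures.  The three-exon layout reuses the exon
#: width/spacing proportions of a well-studied C. elegans three-exon gene
#: (widths 71, 622, 195 within a ~2400-base span); the short-exon case
#: carries a single 28-base exon, the hardest published desk-scale case.
FIXTURE_SPECS: dict[str, SyntheticGeneSpec] = {
    "single_exon": SyntheticGeneSpec(
        total_length=1200, exons=((451, 750),), bias_strength=0.9, seed=42,
        name="single_exon",
    ),
    "three_exon": SyntheticGeneSpec(
        total_length=2400,
        exons=((600, 670), (913, 1534), (1579, 1773)),
        bias_strength=0.9,
        seed=43,
        name="three_exon",
    ),
    "short_exon": SyntheticGeneSpec(
        total_length=900, exons=((437, 464),), bias_strength=1.0,
        codon_profile=POINT_MASS_GTC_PROFILE, seed=44, name="short_exon",
    ),
    "negative_control": SyntheticGeneSpec(
        total_length=1200, exons=(), bias_strength=0.9, seed=45,
        name="negative_control",
    ),
}


def default_fixture_suite(out_dir) -> dict:
    """Write the canonical FASTA/BED fixture pairs and a JSON manifest.

    Returns the manifest (also written to ``manifest.json``): per fixture
    the generating spec and the file names, so a rerun from the manifest
    reproduces identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for key, spec in FIXTURE_SPECS.items():
        seq, ann = generate_gene(spec)
        fasta = out / f"{key}.fasta"
        bed = out / f"{key}.bed"
        write_fasta(fasta, [seq])
        write_bed(bed, ann.intervals, chrom=seq.id)
        manifest[key] = {"spec": spec.to_jsonable(), "fasta": fasta.name, "bed": bed.name}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def simulate_exponentials(
    model: ExponentialsInNoiseModel, N: int, seed: int
) -> ComplexSignal:
    """Simulate x[n] = sum_i |A_i| e^{j(n w_i + phi_i)} + w[n].

    Phases are uniform on [-pi, pi); the noise is circular complex Gaussian
    with variance ``model.noise_variance`` (split evenly between real and
    imaginary parts).
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = np.random.default_rng(seed)
    n = np.arange(N)
    x = np.zeros(N, dtype=np.complex128)
    for w, amp in zip(model.frequencies, model.amplitudes):
        phi = rng.uniform(-np.pi, np.pi)
        x += amp * np.exp(1j * (n * w + phi))
    if model.noise_variance > 0:
        s = np.sqrt(model.noise_variance / 2)
        x += s * (rng.standard_normal(N) + 1j * rng.standard_normal(N))
    return ComplexSignal(values=x, scheme="simulated")
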