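"""Synthetic data with known ground truth for every pipeline stage.

Real inputs to the pipeline — genome-mined ferredoxin sets, CD melts,
electrochemical titrations, oxygen-decay traces, EPR spectra — come from
external databases and instruments.  These generators emulate each of them
from an explicit model so that every downstream estimate can be checked
against planted truth:

* **Duplication–divergence families**: an ancestral half-domain carrying one
  cluster-binding motif is duplicated, fused through a short linker (``VKK``
  or ``DKA``, the linkers of the designed symdoxins), and the two halves
  accumulate independent substitutions at a controlled per-site rate.  The
  paired cophenetic distance measured downstream should grow with that rate.
* **Noisy curves**: direct evaluation of the melt, Nernst and decay models
  plus i.i.d. Gaussian noise scaled to the signal range.
* **Composite spectra**: monomer/dimer basis line shapes built from sums of
  Gaussian-derivative lines, mixed at a set ratio.
* **Genome tables**: joint short x anaerobe labels drawn so that the
  expected enrichment fold equals a planted value.

All generators are pure functions of (parameters, seed) and return their
ground truth alongside the dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .charge import EnrichmentTable
from .fits import MeltModelParams, NernstParams, Spectrum, nernst_fraction, vant_hoff_signal
from .mining import DEFAULT_MOTIF, SequenceRecord

__all__ = [
    "SimConfig",
    "simulate_duplication_divergence",
    "simulate_melt_curve",
    "simulate_titration",
    "simulate_decay",
    "simulate_spectra",
    "simulate_genome_table",
]

#: Residues available for non-ligand positions.  Cys is excluded so each
#: simulated half carries exactly the one planted cluster motif and motif
#: scanning cannot confound the symmetry statistic.
_NON_CYS = "ADEFGHIKLMNPQRSTVWY"


@dataclass
class SimConfig:
    """Parameters of the duplication–divergence and genome-table generators.

    ``rate_per_half`` is the expected substitutions per (mutable) site
    applied independently to each half after duplication; a scalar applies
    to every family, an array gives per-family rates.  Enrichment
    parameters: ``n_genomes`` records with short-sequence probability
    ``p_short``, anaerobe probability ``p_anaerobe`` and planted joint fold
    ``fold`` (the joint cell probability ``fold * p_short * p_anaerobe``
    must stay below both marginals; the defaults plant the ten-fold
    anaerobe enrichment of short sequences at realistic marginals).
    """

    seed: int = 0
    n_families: int = 30
    half_length: int = 26
    motif_start: int = 7
    linker: str = "VKK"
    rate_per_half: float | np.ndarray = 0.1
    noise: float = 0.02
    n_genomes: int = 5000
    p_short: float = 0.05
    p_anaerobe: float = 0.08
    fold: float = 10.0

    def __post_init__(self) -> None:
        rates = np.atleast_1d(np.asarray(self.rate_per_half, dtype=float))
        if np.any(rates < 0) or np.any(rates >= 1):
            raise ValueError("rate_per_half must lie in [0, 1)")
        for name in ("p_short", "p_anaerobe"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def _family_rates(cfg: SimConfig) -> np.ndarray:
    rates = np.atleast_1d(np.asarray(cfg.rate_per_half, dtype=float))
    if rates.size == 1:
        return np.full(cfg.n_families, float(rates[0]))
    if rates.size != cfg.n_families:
        raise ValueError("per-family rates must match n_families")
    return rates


def _random_half(
    rng: np.random.Generator,
    length: int,
    motif: str = DEFAULT_MOTIF,
    start: int | None = None,
) -> tuple[str, list[int]]:
    """An ancestral half-domain with one cluster motif planted; returns the
    sequence and the immutable positions (ligand Cys plus the CP proline).

    ``start`` fixes the motif position (it is positionally conserved across
    real ferredoxin halves); ``None`` places it uniformly at random.
    """
    if length < len(motif):
        raise ValueError("half_length shorter than the motif template")
    seq = list(rng.choice(list(_NON_CYS), size=length))
    if start is None:
        start = int(rng.integers(0, length - len(motif) + 1))
    elif not 0 <= start <= length - len(motif):
        raise ValueError(f"motif start {start} out of range for length {length}")
    protected: list[int] = []
    for off, ch in enumerate(motif):
        pos = start + off
        if ch == ".":
            continue
        seq[pos] = ch
        protected.append(pos)
    return "".join(seq), protected


def _mutate(rng: np.random.Generator, seq: str, rate: float, protected: set[int]) -> str:
    out = list(seq)
    for i in range(len(out)):
        if i in protected:
            continue
        if rng.random() < rate:
            choices = [aa for aa in _NON_CYS if aa != out[i]]
            out[i] = str(rng.choice(choices))
    return "".join(out)


def simulate_duplication_divergence(cfg: SimConfig) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Simulate ferredoxin families arising from half-domain duplication.

    For each family an ancestral half is drawn, duplicated, fused through
    ``cfg.linker``, and each copy is mutated independently at the family's
    per-site rate (motif ligands and the CP dipeptide are immutable).
    Returns the full-length records plus a truth table with the true rate,
    the exact half boundaries and the per-half sequences.
    """
    rng = np.random.default_rng(cfg.seed)
    rates = _family_rates(cfg)
    records: list[SequenceRecord] = []
    rows = []
    for fam, rate in enumerate(rates):
        ancestor, protected = _random_half(rng, cfg.half_length, start=cfg.motif_start)
        prot = set(protected)
        n_half = _mutate(rng, ancestor, rate, prot)
        c_half = _mutate(rng, ancestor, rate, prot)
        full = n_half + cfg.linker + c_half
        fam_id = f"fam{fam:03d}"
        records.append(SequenceRecord(id=fam_id, residues=full))
        rows.append(
            {
                "family_id": fam_id,
                "rate_per_half": float(rate),
                "half_length": cfg.half_length,
                "linker": cfg.linker,
                "n_start": 0,
                "n_end": cfg.half_length,
                "c_start": cfg.half_length + len(cfg.linker),
                "c_end": 2 * cfg.half_length + len(cfg.linker),
                "ancestor": ancestor,
                "n_half": n_half,
                "c_half": c_half,
            }
        )
    return records, pd.DataFrame(rows)


def _add_noise(rng: np.random.Generator, y: np.ndarray, noise: float) -> np.ndarray:
    """Additive Gaussian noise with sigma = noise * (dynamic range of y)."""
    if noise == 0.0:
        return y.copy()
    span = float(y.max() - y.min()) or 1.0
    return y + rng.normal(0.0, noise * span, size=y.shape)


def simulate_melt_curve(
    p: MeltModelParams,
    n_points: int = 40,
    noise: float = 0.0,
    seed: int = 0,
    t_range: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """A thermal-denaturation curve from the two-state melt model.

    The default grid spans Tm +/- 40 K; noise sigma is ``noise`` times the
    clean signal range.
    """
    rng = np.random.default_rng(seed)
    lo, hi = t_range if t_range is not None else (p.Tm - 40.0, p.Tm + 40.0)
    T = np.linspace(lo, hi, n_points)
    y = np.asarray(vant_hoff_signal(T, p), dtype=float)
    return T, _add_noise(rng, y, noise)


def simulate_titration(
    Em: float,
    T: float = 298.0,
    e_grid: np.ndarray | None = None,
    noise: float = 0.0,
    seed: int = 0,
    a_ox: float = 1.0,
    a_red: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """An absorbance-vs-potential titration from the logistic Nernst model.

    Oxidised samples absorb strongly at the Fe-S band and reduction bleaches
    it, so absorbance interpolates from ``a_ox`` (high potential) to
    ``a_red`` (low potential).  The default grid spans Em +/- 150 mV.
    """
    rng = np.random.default_rng(seed)
    E = np.asarray(e_grid, dtype=float) if e_grid is not None else np.linspace(Em - 150.0, Em + 150.0, 25)
    f = np.asarray(nernst_fraction(E, NernstParams(Em=Em, T=T)), dtype=float)
    A = a_ox + (a_red - a_ox) * f
    return E, _add_noise(rng, A, noise)


def simulate_decay(
    half_life: float = 120.0,
    A0: float = 1.0,
    t_grid: np.ndarray | None = None,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """A first-order decay trace; default 0-600 min grid, half-life in min."""
    rng = np.random.default_rng(seed)
    t = np.asarray(t_grid, dtype=float) if t_grid is not None else np.linspace(0.0, 600.0, 61)
    k = np.log(2.0) / half_life
    A = A0 * np.exp(-k * t)
    return t, _add_noise(rng, A, noise)


def _gaussian_derivative_lines(
    field: np.ndarray, lines: list[tuple[float, float, float]]
) -> np.ndarray:
    """Sum of first-derivative Gaussian lines (center mT, width mT, amplitude),
    the standard line shape of a field-modulated CW-EPR spectrum."""
    y = np.zeros_like(field)
    for center, width, amp in lines:
        z = (field - center) / width
        y += -amp * z * np.exp(-0.5 * z * z)
    return y


def simulate_spectra(
    lines_mono: list[tuple[float, float, float]] | None = None,
    lines_dimer: list[tuple[float, float, float]] | None = None,
    mix_ratio: tuple[float, float] = (2.0, 1.0),
    noise: float = 0.0,
    seed: int = 0,
    field_grid: np.ndarray | None = None,
) -> tuple[Spectrum, Spectrum, Spectrum, dict]:
    """Monomer/dimer basis spectra and their mixed composite.

    Bases are sums of Gaussian-derivative lines on a shared field grid; the
    composite is ``w_m * B_m + w_d * B_d`` at the requested mix ratio plus
    optional noise.  Default lines place a sharp single-cluster feature near
    g ~ 1.94 (340 mT band) for the monomer and broader, split features for
    the spin-coupled dimer.  Returns (basis_mono, basis_dimer, composite,
    truth).
    """
    rng = np.random.default_rng(seed)
    field = (
        np.asarray(field_grid, dtype=float)
        if field_grid is not None
        else np.linspace(300.0, 360.0, 601)
    )
    if lines_mono is None:
        lines_mono = [(335.0, 2.0, 1.0), (345.0, 3.0, 0.6)]
    if lines_dimer is None:
        lines_dimer = [(325.0, 5.0, 0.8), (340.0, 6.0, 0.5), (352.0, 4.0, 0.4)]
    b_mono = _gaussian_derivative_lines(field, lines_mono)
    b_dimer = _gaussian_derivative_lines(field, lines_dimer)
    w_m, w_d = float(mix_ratio[0]), float(mix_ratio[1])
    composite = w_m * b_mono + w_d * b_dimer
    composite = _add_noise(rng, composite, noise)
    truth = {"w_mono": w_m, "w_dimer": w_d, "mix_ratio": w_m / w_d if w_d else np.inf}
    return (
        Spectrum(field=field, intensity=b_mono),
        Spectrum(field=field, intensity=b_dimer),
        Spectrum(field=field, intensity=composite),
        truth,
    )


def _joint_probs(p_short: float, p_anaerobe: float, fold: float) -> np.ndarray:
    """Cell probabilities [short&ana, short&aero, long&ana, long&aero] with
    the joint cell planted at fold x independence."""
    p11 = fold * p_short * p_anaerobe
    p10 = p_short - p11
    p01 = p_anaerobe - p11
    p00 = 1.0 - p_short - p_anaerobe + p11
    probs = np.array([p11, p10, p01, p00])
    if np.any(probs < 0) or np.any(probs > 1):
        raise ValueError(
            f"fold {fold} is infeasible at marginals p_short={p_short}, "
            f"p_anaerobe={p_anaerobe}"
        )
    return probs


def simulate_genome_table(
    cfg: SimConfig, with_sequences: bool = True
) -> tuple[EnrichmentTable, pd.DataFrame, list[SequenceRecord]]:
    """A genome metadata table with planted short x anaerobe enrichment.

    Each record draws joint (short, anaerobe) labels from the four-cell
    distribution whose joint probability is ``fold`` times the product of
    the marginals.  Alongside the contingency counts and the per-record
    label table, sequence records are emitted for the mining stage: short
    records are semidoxin-sized with one planted motif, long records carry
    two motifs (a duplicated half and linker).  ``with_sequences=False``
    skips sequence emission (label draws are unchanged) for replicate
    studies that only need the counts.
    """
    rng = np.random.default_rng(cfg.seed)
    probs = _joint_probs(cfg.p_short, cfg.p_anaerobe, cfg.fold)
    cells = rng.choice(4, size=cfg.n_genomes, p=probs)
    short = np.isin(cells, (0, 1))
    anaerobe = np.isin(cells, (0, 2))
    table = EnrichmentTable(
        n_total=cfg.n_genomes,
        n_short=int(short.sum()),
        n_anaerobe=int(anaerobe.sum()),
        n_short_and_anaerobe=int((short & anaerobe).sum()),
    )
    # a full-length record must clear the 60-aa "short" bound after fusion
    long_half = max(cfg.half_length, -(-(60 - len(cfg.linker)) // 2))
    records: list[SequenceRecord] = []
    rows = []
    for i in range(cfg.n_genomes):
        sid = f"seq{i:05d}"
        rows.append({"seq_id": sid, "short": bool(short[i]), "anaerobe": bool(anaerobe[i])})
        if not with_sequences:
            continue
        oxy = "anaerobe" if anaerobe[i] else "aerobe"
        if short[i]:
            residues, _ = _random_half(rng, cfg.half_length)
        else:
            half, _ = _random_half(rng, long_half)
            residues = half + cfg.linker + half
        records.append(SequenceRecord(id=sid, residues=residues, oxygen_class=oxy))
    return table, pd.DataFrame(rows), records
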