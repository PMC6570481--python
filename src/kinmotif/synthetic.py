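"""Synthetic ground truth for exercising the pipeline end to end.

Real oriented-peptide-library blots, phosphosite databases and assay time
courses are not required anywhere in the test suite: this module generates
(i) ground-truth motifs in the normalized space the pipeline recovers,
(ii) noisy replicate spot grids with per-blot exposure scaling and
multiplicative lognormal spot noise, (iii) candidate-site databases of
background windows plus motif-matching implants, and (iv) linear
phosphorylation time courses with Gaussian counting noise.

All generators are pure functions of their parameters and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alphabet import ACCEPTORS, AMINO_ACIDS, GRID_RESIDUES, POSITIONS
from .errors import ParameterError
from .kinetics import TimeCourse
from .opls import MotifMatrix, SpotGrid
from .scoring import CandidateSite


@dataclass
class NoiseModel:
    """Replicate-to-replicate variability of a dot-blot readout.

    ``sigma_log``: std-dev of multiplicative lognormal noise per spot.
    ``blot_scale_range``: uniform range for the per-replicate global
    exposure factor (the column-mean normalization is exactly invariant to
    it, which is the property the pipeline exploits).
    """

    sigma_log: float = 0.1
    blot_scale_range: tuple[float, float] = (0.5, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_log < 0:
            raise ParameterError(f"sigma_log must be >= 0, got {self.sigma_log}")
        lo, hi = self.blot_scale_range
        if not (0 < lo <= hi):
            raise ParameterError(f"invalid blot_scale_range {self.blot_scale_range}")


@dataclass
class SiteDatabaseSpec:
    """Shape of a synthetic candidate-phosphosite database."""

    n_background: int = 1900
    n_implanted_per_kinase: int = 100
    background_freqs: dict[str, float] | None = None  # default: uniform over 20 AA
    acceptor_rule: str = "S"  # acceptor residue carried by every generated site
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_background < 0 or self.n_implanted_per_kinase < 0:
            raise ParameterError("site counts must be >= 0")
        if self.acceptor_rule not in ACCEPTORS:
            raise ParameterError(f"acceptor_rule must be one of {ACCEPTORS}")
        if self.background_freqs is not None:
            unknown = set(self.background_freqs) - set(AMINO_ACIDS)
            if unknown:
                raise ParameterError(f"background_freqs has non-amino-acid keys {sorted(unknown)}")
            total = sum(self.background_freqs.values())
            if not np.isclose(total, 1.0):
                raise ParameterError(f"background_freqs must sum to 1, got {total}")

    def freq_vector(self) -> np.ndarray:
        if self.background_freqs is None:
            return np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
        return np.array([self.background_freqs.get(a, 0.0) for a in AMINO_ACIDS])


@dataclass
class TrueMotif:
    """Ground-truth motif stored in normalized space (position means = 1)."""

    kinase_id: str
    values: pd.DataFrame  # positions x 22 residues, strictly positive
    acceptor_pref: pd.Series  # S/T/Y probabilities summing to 1
    selective_positions: dict[int, str] = field(default_factory=dict)

    def as_motif_matrix(self, stage: str = "averaged") -> MotifMatrix:
        """View the truth as a pipeline-stage matrix (it lives in normalized space)."""
        return MotifMatrix(
            kinase_id=self.kinase_id,
            library="ST",
            stage=stage,  # type: ignore[arg-type]
            values=self.values.copy(),
            acceptor_pref=self.acceptor_pref * len(self.acceptor_pref.dropna()),
            n_replicates=0,
        )


def make_true_motif(
    kinase_id: str,
    n_selective_positions: int = 4,
    preference_strength: float = 5.0,
    acceptor_pref: dict[str, float] | None = None,
    seed: int = 0,
) -> TrueMotif:
    """Generate a ground-truth motif with a few strongly selective positions.

    Each selective position favors one randomly chosen residue whose
    normalized value exceeds ``preference_strength`` times the position's
    median; the remaining positions are flat (all values 1).  Positions are
    renormalized to mean 1, the space the normalization pipeline recovers.
    """
    if preference_strength <= 0:
        raise ParameterError(f"preference_strength must be > 0, got {preference_strength}")
    if not 0 <= n_selective_positions <= len(POSITIONS):
        raise ParameterError(
            f"n_selective_positions must be in [0, {len(POSITIONS)}], got {n_selective_positions}"
        )
    rng = np.random.default_rng(seed)
    values = pd.DataFrame(
        1.0, index=pd.Index(POSITIONS, name="position"), columns=list(GRID_RESIDUES)
    )
    chosen = sorted(rng.choice(POSITIONS, size=n_selective_positions, replace=False).tolist())
    selective: dict[int, str] = {}
    for pos in chosen:
        # Favor a plain amino acid so implanted sites can carry the residue.
        res = str(rng.choice(AMINO_ACIDS))
        values.at[pos, res] = float(preference_strength)
        selective[pos] = res
    values = values.div(values.mean(axis=1), axis=0)  # store in normalized space
    if acceptor_pref is None:
        acceptor_pref = {"S": 0.45, "T": 0.45, "Y": 0.10}
    pref = pd.Series(acceptor_pref, dtype=float).reindex(list(ACCEPTORS)).fillna(0.0)
    if (pref < 0).any() or not np.isclose(pref.sum(), 1.0):
        raise ParameterError(f"acceptor_pref must be nonnegative and sum to 1, got {dict(pref)}")
    return TrueMotif(kinase_id=kinase_id, values=values, acceptor_pref=pref, selective_positions=selective)


def simulate_spot_grids(
    truth: TrueMotif, noise: NoiseModel, n_replicates: int = 2
) -> list[SpotGrid]:
    """Simulate raw replicate spot grids from a ground-truth motif.

    Each replicate draws one global blot scale, then every spot is
    ``scale * truth * exp(N(0, sigma_log))``.  Acceptor pools are generated
    the same way from the acceptor preference (rescaled to mean 1 so the
    zero-noise round trip is exact).  Raw grids are NOT normalized.
    """
    if n_replicates < 1:
        raise ParameterError(f"n_replicates must be >= 1, got {n_replicates}")
    rng = np.random.default_rng(noise.seed)
    lo, hi = noise.blot_scale_range
    grids = []
    # Acceptor truth in "normalized" space: mean of the three pools = 1.
    acc_truth = truth.acceptor_pref * len(ACCEPTORS)
    for rep in range(n_replicates):
        scale = float(rng.uniform(lo, hi))
        flank_noise = np.exp(rng.normal(0.0, noise.sigma_log, size=truth.values.shape))
        flank = truth.values * flank_noise * scale
        acc_noise = np.exp(rng.normal(0.0, noise.sigma_log, size=len(ACCEPTORS)))
        acceptor = acc_truth * acc_noise * scale
        grids.append(
            SpotGrid(
                kinase_id=truth.kinase_id,
                library="ST",
                replicate_id=f"rep{rep + 1}",
                flank=flank,
                acceptor=acceptor,
            )
        )
    return grids


def _implant_probabilities(motif: TrueMotif) -> pd.DataFrame:
    """Per-position sampling probabilities over the 20 amino acids."""
    cols = motif.values[list(AMINO_ACIDS)]
    return cols.div(cols.sum(axis=1), axis=0)


def simulate_site_database(
    spec: SiteDatabaseSpec, implant_motifs: list[TrueMotif] | None = None
) -> list[CandidateSite]:
    """Generate background sites plus motif-matching implants.

    Background windows are i.i.d. draws from ``background_freqs`` over the
    20 amino acids; implanted windows draw each flank residue from the
    motif's position profile renormalized to probabilities, so stronger
    preferences yield closer motif matches.  Implants are identifiable by
    protein ids of the form ``IMP_<kinase>_<k>``; backgrounds are ``BG<k>``.
    Every site has a unique (protein_id, position) key.
    """
    implant_motifs = implant_motifs or []
    if spec.n_background + spec.n_implanted_per_kinase * len(implant_motifs) == 0:
        raise ParameterError("site database would be empty")
    freqs = spec.freq_vector()
    if freqs.sum() == 0:
        raise ParameterError("background_freqs assigns zero mass to every residue")
    freqs = freqs / freqs.sum()
    rng = np.random.default_rng(spec.seed)
    aa = np.array(AMINO_ACIDS)
    sites: list[CandidateSite] = []
    draws = rng.choice(len(aa), size=(spec.n_background, len(POSITIONS)), p=freqs)
    for i in range(spec.n_background):
        window = "".join(aa[draws[i]])
        sites.append(
            CandidateSite(
                protein_id=f"BG{i:06d}",
                site_position=10 + i,
                acceptor_residue=spec.acceptor_rule,
                window=window,
            )
        )
    for motif in implant_motifs:
        probs = _implant_probabilities(motif)
        for i in range(spec.n_implanted_per_kinase):
            window = "".join(
                str(rng.choice(aa, p=probs.loc[pos].to_numpy())) for pos in POSITIONS
            )
            sites.append(
                CandidateSite(
                    protein_id=f"IMP_{motif.kinase_id}_{i:04d}",
                    site_position=10 + i,
                    acceptor_residue=spec.acceptor_rule,
                    window=window,
                )
            )
    return sites


def simulate_timecourse(
    rate: float,
    intercept: float,
    timepoints: list[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str = "peptide",
    replicate_id: str = "rep1",
) -> TimeCourse:
    """Linear phosphorylation time course with Gaussian counting noise."""
    if noise_sd < 0:
        raise ParameterError(f"noise_sd must be >= 0, got {noise_sd}")
    times = np.asarray(timepoints, dtype=float)
    if len(np.unique(times)) < 2:
        raise ParameterError("need at least 2 distinct timepoints")
    rng = np.random.default_rng(seed)
    counts = intercept + rate * times + rng.normal(0.0, noise_sd, size=times.shape)
    return TimeCourse(label=label, replicate_id=replicate_id, times=times, counts=counts)
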