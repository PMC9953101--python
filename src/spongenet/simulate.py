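"""Synthetic two-group expression data with planted ceRNA structure.

Generates lncRNA / miRNA / mRNA abundance matrices (FPKM-like, log-normal)
for a heat-stress vs. control design, together with the ground truth that
was planted: which transcripts are differentially expressed and which
(lncRNA, miRNA, mRNA) triplets form a competing-endogenous-RNA relationship
(the miRNA targets both the lncRNA and the mRNA, expression of the miRNA is
negatively coupled to both, hence the lncRNA and mRNA are positively
coupled). Decoy miRNA->target annotations without any expression coupling
are planted alongside, so downstream filters have something to reject.

Generative model, per tissue, on the log2 scale (sample s, indicator
h(s) = 1 for the stressed group):

    miRNA i:   m_i(s) = mu_i + delta_i * h(s) + u_i(s),  u ~ N(0, signal_sd^2)
               observed log2 value = m_i(s) + eps,       eps ~ N(0, noise_sd^2)
    coupled target t of i:
               x_t(s) = mu_t - beta * z_i(s) + d_t * h(s) + eps
    uncoupled transcript t:
               x_t(s) = mu_t + delta_t * h(s) + eps

where z_i is the within-matrix standardization of m_i across samples and
the direct shift d_t is chosen so that the total expected group shift of a
coupled target equals its true log2 fold change (the miRNA channel alone
already moves a coupled target by -beta * E[dz], which d_t compensates).
Abundances are emitted as 2**x, so they are strictly positive.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleDesign",
    "SimulationParams",
    "GroundTruth",
    "compute_thi",
    "make_design",
    "generate_truth",
    "simulate_expression",
    "write_fixture_bundle",
]

GROUPS = ("NHS", "HS")
TISSUES = ("hypothalamus", "pituitary", "mammary")


def compute_thi(T, RH):
    """Temperature-humidity index for cattle heat-stress assessment.

    THI = (1.8*T + 32) - (0.55 - 0.55*RH) * (1.8*T - 26)

    Parameters
    ----------
    T : float or array
        Dry-bulb temperature in degrees Celsius.
    RH : float or array
        Relative humidity as a *fraction* in [0, 1] (pass 0.70 for 70%).

    Returns
    -------
    float or array — dimensionless index (>= 72 marks heat-stress onset).
    """
    T = np.asarray(T, dtype=float)
    RH = np.asarray(RH, dtype=float)
    if not np.all(np.isfinite(T)):
        raise ValueError("temperature must be finite")
    if np.any(RH < 0.0) or np.any(RH > 1.0):
        raise ValueError(
            "RH must be a fraction in [0, 1]; divide percent values by 100"
        )
    thi = (1.8 * T + 32.0) - (0.55 - 0.55 * RH) * (1.8 * T - 26.0)
    if thi.ndim == 0:
        return float(thi)
    return thi


@dataclass(frozen=True)
class SampleDesign:
    """One sample: id, group (NHS control / HS heat-stressed) and tissue."""

    sample_id: str
    group: str
    tissue: str

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.tissue not in TISSUES:
            raise ValueError(f"tissue must be one of {TISSUES}, got {self.tissue!r}")


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the planted-truth simulator.

    All log-scale quantities are in log2 units. ``signal_sd`` is the SD of
    the latent per-sample miRNA activity (the biological signal that the
    sponge coupling propagates); ``noise_sd`` is the measurement noise added
    to every observed value.
    """

    n_per_group: int = 10
    n_lnc: int = 150
    n_mir: int = 100
    n_mrna: int = 150
    n_triplets: int = 20
    n_decoys: int = 200
    de_fraction: float = 0.3
    lfc_magnitude: float = 2.0
    coupling_beta: float = 1.5
    noise_sd: float = 0.3
    signal_sd: float = 0.8
    baseline_log_mean: float = 6.0
    baseline_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_per_group", "n_lnc", "n_mir", "n_mrna"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_triplets < 0 or self.n_decoys < 0:
            raise ValueError("n_triplets and n_decoys must be >= 0")
        if self.n_triplets > min(self.n_lnc, self.n_mrna):
            raise ValueError(
                "n_triplets exceeds available lncRNA/mRNA ids: "
                f"{self.n_triplets} > min({self.n_lnc}, {self.n_mrna})"
            )
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")
        if self.noise_sd < 0 or self.signal_sd < 0:
            raise ValueError("standard deviations must be >= 0")


@dataclass
class GroundTruth:
    """What the simulator planted: DE labels, ceRNA triplets, annotations.

    ``de_transcripts`` maps transcript id -> true log2 fold change (HS over
    NHS). ``triplets`` lists (lnc_id, mir_id, mrna_id). ``target_table``
    holds every annotated miRNA->target pair, planted and decoy alike, with
    columns (mirna_id, target_id, target_class).
    """

    de_transcripts: dict[str, float]
    triplets: list[tuple[str, str, str]]
    target_table: pd.DataFrame

    def de_ids(self) -> set[str]:
        return set(self.de_transcripts)

    def true_sponge_pairs(self) -> set[tuple[str, str]]:
        """The (lnc_id, mrna_id) pairs a perfect network would recover."""
        return {(l, m) for l, _, m in self.triplets}


def make_design(n_per_group: int, tissue: str = "mammary") -> list[SampleDesign]:
    """Balanced two-group design for one tissue (ids like HS_M1, NHS_M2)."""
    code = {"hypothalamus": "H", "pituitary": "P", "mammary": "M"}[tissue]
    design = []
    for group in GROUPS:
        for i in range(1, n_per_group + 1):
            design.append(SampleDesign(f"{group}_{code}{i}", group, tissue))
    return design


def _ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(1, n + 1)]


def generate_truth(params: SimulationParams) -> GroundTruth:
    """Draw the planted structure: triplets, decoy annotations, DE labels.

    Triplet lncRNA and mRNA members are disjoint across triplets; miRNAs are
    drawn without replacement while possible. Every triplet member is marked
    differentially expressed (the sponge-network filters require it), with
    the lncRNA/mRNA shifted opposite to their miRNA. Beyond that,
    floor(de_fraction * n) transcripts per class are DE with random sign.
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 17]))
    lnc_ids = _ids("LNC", params.n_lnc)
    mir_ids = _ids("MIR", params.n_mir)
    mrna_ids = _ids("MRNA", params.n_mrna)

    t_lnc = list(rng.choice(lnc_ids, size=params.n_triplets, replace=False))
    t_mrna = list(rng.choice(mrna_ids, size=params.n_triplets, replace=False))
    if params.n_triplets <= params.n_mir:
        t_mir = list(rng.choice(mir_ids, size=params.n_triplets, replace=False))
    else:
        t_mir = list(rng.choice(mir_ids, size=params.n_triplets, replace=True))
    triplets = list(zip(t_lnc, t_mir, t_mrna))

    # DE labels: triplet members always; others sampled to the class quota.
    de: dict[str, float] = {}
    mir_sign = {m: float(rng.choice([-1.0, 1.0])) for m in t_mir}
    for lnc, mir, mrna in triplets:
        s = mir_sign[mir]
        de[mir] = s * params.lfc_magnitude
        de[lnc] = -s * params.lfc_magnitude
        de[mrna] = -s * params.lfc_magnitude
    for ids in (lnc_ids, mir_ids, mrna_ids):
        quota = math.floor(params.de_fraction * len(ids))
        pool = [i for i in ids if i not in de]
        n_extra = max(0, quota - (len(ids) - len(pool)))
        extra = rng.choice(pool, size=min(n_extra, len(pool)), replace=False)
        for t in extra:
            de[t] = float(rng.choice([-1.0, 1.0])) * params.lfc_magnitude

    rows = [
        {"mirna_id": mir, "target_id": lnc, "target_class": "lncRNA"}
        for lnc, mir, _ in triplets
    ] + [
        {"mirna_id": mir, "target_id": mrna, "target_class": "mRNA"}
        for _, mir, mrna in triplets
    ]
    planted = {(r["mirna_id"], r["target_id"]) for r in rows}
    # Decoy annotations: uniform (miRNA, target) pairs with no expression
    # coupling, deduplicated against planted pairs and each other.
    all_targets = [(t, "lncRNA") for t in lnc_ids] + [(t, "mRNA") for t in mrna_ids]
    seen = set(planted)
    guard = 0
    while len(seen) - len(planted) < params.n_decoys:
        guard += 1
        if guard > 50 * max(params.n_decoys, 1):
            raise ValueError("cannot place requested decoys without duplicates")
        mir = mir_ids[int(rng.integers(len(mir_ids)))]
        tgt, cls = all_targets[int(rng.integers(len(all_targets)))]
        if (mir, tgt) in seen:
            continue
        seen.add((mir, tgt))
        rows.append({"mirna_id": mir, "target_id": tgt, "target_class": cls})

    table = pd.DataFrame(rows, columns=["mirna_id", "target_id", "target_class"])
    return GroundTruth(de_transcripts=de, triplets=triplets, target_table=table)


def _simulate_class(
    ids: Sequence[str],
    design: Sequence[SampleDesign],
    truth: GroundTruth,
    params: SimulationParams,
    rng: np.random.Generator,
    latent_mir: dict[str, np.ndarray] | None,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """One class's log2 matrix for one tissue. Returns (matrix, miRNA latents).

    When ``latent_mir`` is None the class *is* the miRNA class and the
    latent signals are generated here; otherwise coupled targets read their
    miRNA's latent from the mapping.
    """
    n = len(design)
    h = np.array([1.0 if s.group == "HS" else 0.0 for s in design])
    coupled_to = {}
    if latent_mir is not None:
        for lnc, mir, mrna in truth.triplets:
            coupled_to[lnc] = mir
            coupled_to[mrna] = mir
    mu = rng.normal(params.baseline_log_mean, params.baseline_log_sd, size=len(ids))
    log2 = np.empty((len(ids), n))
    latents: dict[str, np.ndarray] = {}
    for row, tid in enumerate(ids):
        delta = truth.de_transcripts.get(tid, 0.0)
        eps = rng.normal(0.0, params.noise_sd, size=n) if params.noise_sd > 0 else 0.0
        if latent_mir is None:
            u = rng.normal(0.0, params.signal_sd, size=n) if params.signal_sd > 0 else np.zeros(n)
            m = mu[row] + delta * h + u
            latents[tid] = m
            log2[row] = m + eps
        elif tid in coupled_to:
            mir_id = coupled_to[tid]
            m = latent_mir[mir_id]
            sd = m.std()
            z = (m - m.mean()) / sd if sd > 0 else np.zeros(n)
            mir_delta = truth.de_transcripts.get(mir_id, 0.0)
            if delta == 0.0 and mir_delta == 0.0:
                # No planted group effect anywhere in the pair: leave the
                # coupling pure (the exact-anti-monotone limit).
                log2[row] = mu[row] - params.coupling_beta * z + eps
            else:
                # Direct shift compensates the miRNA-channel group shift so
                # the realized group log2FC equals the planted true_log2fc.
                n_hs = max(int(h.sum()), 1)
                n_nhs = max(n - int(h.sum()), 1)
                dz = z[h == 1].sum() / n_hs - z[h == 0].sum() / n_nhs
                d_direct = delta + params.coupling_beta * dz
                log2[row] = mu[row] - params.coupling_beta * z + d_direct * h + eps
        else:
            log2[row] = mu[row] + delta * h + eps
    cols = [s.sample_id for s in design]
    return pd.DataFrame(np.exp2(log2), index=list(ids), columns=cols), latents


def simulate_expression(
    truth: GroundTruth,
    design: Sequence[SampleDesign],
    params: SimulationParams,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Abundance matrices (lncRNA, miRNA, mRNA) for every sample in design.

    Samples of different tissues are simulated independently (fresh latents
    and noise per tissue) but share the same planted truth, mirroring a
    study that profiles the same animals' tissues separately. Matrices are
    FPKM-like: strictly positive, log-normal around 2**baseline_log_mean.
    """
    design = list(design)
    if not design:
        raise ValueError("design must contain at least one sample")
    if len({s.sample_id for s in design}) != len(design):
        raise ValueError("sample_ids must be unique")
    for tissue in {s.tissue for s in design}:
        sub = [s for s in design if s.tissue == tissue]
        for g in GROUPS:
            if sum(1 for s in sub if s.group == g) < 2:
                raise ValueError(
                    f"tissue {tissue!r} needs >= 2 samples in group {g}"
                )

    lnc_ids = _ids("LNC", params.n_lnc)
    mir_ids = _ids("MIR", params.n_mir)
    mrna_ids = _ids("MRNA", params.n_mrna)
    lnc_parts, mir_parts, mrna_parts = [], [], []
    # Deterministic per-tissue streams, in canonical tissue order.
    for t_idx, tissue in enumerate(TISSUES):
        sub = [s for s in design if s.tissue == tissue]
        if not sub:
            continue
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, 29, t_idx]))
        mir_m, latents = _simulate_class(mir_ids, sub, truth, params, rng, None)
        lnc_m, _ = _simulate_class(lnc_ids, sub, truth, params, rng, latents)
        mrna_m, _ = _simulate_class(mrna_ids, sub, truth, params, rng, latents)
        mir_parts.append(mir_m)
        lnc_parts.append(lnc_m)
        mrna_parts.append(mrna_m)
    order = [s.sample_id for s in design]
    lnc = pd.concat(lnc_parts, axis=1)[order]
    mir = pd.concat(mir_parts, axis=1)[order]
    mrna = pd.concat(mrna_parts, axis=1)[order]
    for m in (lnc, mir, mrna):
        m.index.name = "transcript_id"
    return lnc, mir, mrna


def write_fixture_bundle(
    truth: GroundTruth,
    design: Sequence[SampleDesign],
    matrices: tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame],
    out_dir: str | Path,
    params: SimulationParams | None = None,
) -> list[Path]:
    """Write the full bundle as TSV (+ a JSON parameter record).

    Returns the manifest of written files. Deterministic: same inputs give
    byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lnc, mir, mrna = matrices
    manifest = []

    def _write_matrix(df: pd.DataFrame, name: str):
        p = out / name
        df.rename_axis("transcript_id").to_csv(
            p, sep="\t", float_format="%.10g", lineterminator="\n"
        )
        manifest.append(p)

    _write_matrix(lnc, "lncRNA.tsv")
    _write_matrix(mir, "miRNA.tsv")
    _write_matrix(mrna, "mRNA.tsv")

    p = out / "design.tsv"
    pd.DataFrame(
        [(s.sample_id, s.group, s.tissue) for s in design],
        columns=["sample_id", "group", "tissue"],
    ).to_csv(p, sep="\t", index=False, lineterminator="\n")
    manifest.append(p)

    p = out / "targets.tsv"
    truth.target_table.to_csv(p, sep="\t", index=False, lineterminator="\n")
    manifest.append(p)

    p = out / "truth_de.tsv"
    pd.DataFrame(
        sorted(truth.de_transcripts.items()),
        columns=["transcript_id", "true_log2fc"],
    ).to_csv(p, sep="\t", index=False, float_format="%.10g", lineterminator="\n")
    manifest.append(p)

    p = out / "truth_triplets.tsv"
    pd.DataFrame(
        truth.triplets, columns=["lnc_id", "mirna_id", "mrna_id"]
    ).to_csv(p, sep="\t", index=False, lineterminator="\n")
    manifest.append(p)

    if params is not None:
        p = out / "params.json"
        p.write_text(json.dumps(asdict(params), indent=2, sort_keys=True) + "\n")
        manifest.append(p)
    return manifest
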