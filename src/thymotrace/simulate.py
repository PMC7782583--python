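"""Ground-truthed synthetic thymocyte scRNA-seq generator.

Emulates deep (SMART-seq-like) single-cell counts over a CD4/CD8 lineage
choice trajectory: each cell carries a latent maturation time in [0, 1] and
an eventual lineage branch; gene means follow per-program kinetics
(maturation genes monotone in time, activation genes a transient mid-
trajectory pulse, lineage genes a branch-gated late sigmoid, housekeeping
flat) and the coreceptor genes Cd4/Cd8a/Cd8b1 follow piecewise on/off
windows. Two timing regimes are supported:

* ``sequential`` — all signalled cells first shut off *Cd8a* (the
  Cd4+Cd8a- audition stage); CD8-fated cells later shut off *Cd4* and
  re-express *Cd8a*, so Cd4+Cd8a- intermediates appear before Cd4-Cd8a+
  intermediates along maturation.
* ``simultaneous`` — CD4-fated cells shut off *Cd8a* and CD8-fated cells
  shut off *Cd4* at the same time, so the two single-positive transcript
  states arise together (the MHC class II-deficient-like regime).

Counts are negative binomial around the kinetic means, scaled to a target
library size, then zeroed independently per gene with a per-program dropout
probability.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Union

import numpy as np
import pandas as pd

from .io import write_gene_set
from .types import CellAnnotation, CountMatrix, GeneSetRef, PHENOTYPES

CORECEPTOR_GENES = ("Cd4", "Cd8a", "Cd8b1")

#: Gene programs and their default partition sizes (sums to n_genes=500).
DEFAULT_PROGRAM_SIZES: dict[str, int] = {
    "coreceptor": 3,
    "maturation_up": 80,
    "maturation_down": 80,
    "activation_pulse": 80,
    "cd4_lineage": 40,
    "cd8_lineage": 40,
    "housekeeping": 177,
}

#: Developmental stage index per sort phenotype (both SP subsets share the
#: final stage; the branch, not the time window, separates them).
_STAGE = {
    "CD69neg_DP": 0,
    "CD69pos_DP": 1,
    "TCRbhi_DP": 2,
    "CD4_CD8low": 3,
    "CD4_SP": 4,
    "CD8_SP": 4,
}
_N_STAGES = 5


@dataclass(frozen=True)
class Kinetics:
    """Kinetic constants of the gene programs (count-mean scale).

    Amplitudes are chosen so the variance decomposition of the simulated
    data is dominated by maturation, then activation, then lineage, the
    ordering the analysis assumes for PC1/PC2/PC3.
    """

    maturation_fold: float = 8.0
    maturation_center: float = 0.5
    maturation_steepness: float = 6.0
    activation_amplitude: float = 6.0
    activation_center: float = 0.5
    activation_width: float = 0.15
    lineage_fold: float = 6.0
    lineage_onset: float = 0.75
    lineage_steepness: float = 12.0
    coreceptor_on_mean: float = 2000.0
    # steep enough that the detectable range of a coreceptor gene matches
    # its on-window to within ~0.02 of the time axis (near-binary detection)
    coreceptor_steepness: float = 400.0
    # coreceptor switch times (fractions of the maturation axis)
    # switch times span the intermediate sort windows so that CD69+ DP are
    # mostly Cd4+Cd8a+ with emerging Cd4+Cd8a-, TCRbhi DP mix all three
    # classes and CD4+CD8low split between the single-positive states
    seq_cd8a_off: float = 0.35  # all branches: Cd8a off -> Cd4+Cd8a- audition
    seq_cd4_off: float = 0.55  # CD8 branch: Cd4 off / Cd8a back on
    sim_switch: float = 0.55  # simultaneous regime: both switches coincide
    baseline_log_mean: float = float(np.log(800.0))
    baseline_log_sd: float = 0.8
    stage_overlap: float = 0.10  # fractional overlap of adjacent stage windows


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset."""

    n_cells_per_subset: Union[int, Mapping[str, int]] = 50
    n_genes: int = 500
    program_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PROGRAM_SIZES)
    )
    coreceptor_timing: str = "sequential"
    # coreceptor transcripts are detected in 92-99% of cells that should
    # express them at SMART-seq depth; other programs drop out a bit more
    dropout_rate: Union[float, Mapping[str, float]] = field(
        default_factory=lambda: {
            "coreceptor": 0.03,
            "maturation_up": 0.05,
            "maturation_down": 0.05,
            "activation_pulse": 0.05,
            "cd4_lineage": 0.05,
            "cd8_lineage": 0.05,
            "housekeeping": 0.05,
        }
    )
    nb_dispersion: float = 2.0
    library_size_mean: float = 1_000_000.0
    activation_scale: float = 1.0
    cd4_lineage_silenced: bool = False
    condition: str = "WT"
    batch: str = "B1"
    seed: int = 0
    kinetics: Kinetics = field(default_factory=Kinetics)

    def validate(self) -> None:
        if self.coreceptor_timing not in ("sequential", "simultaneous"):
            raise ValueError(
                f"coreceptor_timing must be 'sequential' or 'simultaneous', "
                f"got {self.coreceptor_timing!r}"
            )
        sizes = dict(self.program_sizes)
        if sizes.get("coreceptor", 0) != len(CORECEPTOR_GENES):
            raise ValueError(
                f"program_sizes['coreceptor'] must be {len(CORECEPTOR_GENES)}"
            )
        total = sum(sizes.values())
        if total != self.n_genes:
            raise ValueError(
                f"program partition sizes sum to {total}, not n_genes={self.n_genes}"
            )
        for prog, rate in self._dropout_by_program().items():
            if not (0.0 <= rate < 1.0):
                raise ValueError(f"dropout_rate for {prog!r} must be in [0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.activation_scale < 0:
            raise ValueError("activation_scale must be non-negative")

    def _dropout_by_program(self) -> dict[str, float]:
        progs = list(self.program_sizes)
        if isinstance(self.dropout_rate, Mapping):
            return {p: float(self.dropout_rate.get(p, 0.0)) for p in progs}
        return {p: float(self.dropout_rate) for p in progs}

    def cells_per_subset(self) -> dict[str, int]:
        if isinstance(self.n_cells_per_subset, Mapping):
            return {p: int(self.n_cells_per_subset.get(p, 0)) for p in PHENOTYPES}
        return {p: int(self.n_cells_per_subset) for p in PHENOTYPES}


def mhcii_ko_config(base: SimulationConfig, activation_scale: float = 0.5) -> SimulationConfig:
    """Derive the MHC class II-deficient condition from a wild-type config.

    The knockout is modelled as simultaneous coreceptor timing, a reduced
    activation-pulse amplitude (weaker TCR signals when ligands are
    restricted to MHC class I) and a silenced CD4-lineage program (the CD4
    lineage-specifying factor is absent without MHC class II).
    """
    return replace(
        base,
        coreceptor_timing="simultaneous",
        activation_scale=activation_scale,
        cd4_lineage_silenced=True,
        condition="MHCII_KO",
    )


@dataclass
class GroundTruth:
    """Latent variables behind a simulated dataset."""

    true_time: np.ndarray
    true_state: np.ndarray
    branch: np.ndarray
    program_of_gene: pd.Series
    truth_genesets: dict[str, GeneSetRef]


# ---------------------------------------------------------------------------
# kinetics


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _ramp(t: np.ndarray, center: float, steepness: float) -> np.ndarray:
    """Logistic ramp normalised to hit exactly 0 at t=0 and 1 at t=1."""
    lo = _sigmoid(-steepness * center)
    hi = _sigmoid(steepness * (1.0 - center))
    return (_sigmoid(steepness * (np.asarray(t, float) - center)) - lo) / (hi - lo)


def _window(t: np.ndarray, t_on: float, t_off: float, steepness: float) -> np.ndarray:
    """Smooth indicator of the interval [t_on, t_off)."""
    return _sigmoid(steepness * (np.asarray(t, float) - t_on)) * _sigmoid(
        steepness * (t_off - np.asarray(t, float))
    )


def coreceptor_windows(
    gene: str, branch: str, timing: str, kin: Kinetics
) -> list[tuple[float, float]]:
    """On-intervals of a coreceptor gene for a branch under a timing regime.

    Intervals extend beyond [0, 1] where the gene is on from the start or
    stays on to the end, so the smooth window equals 1 at the boundaries.
    """
    always = [(-1.0, 2.0)]
    if gene == "Cd4":
        if branch == "CD4":
            return always
        off = kin.seq_cd4_off if timing == "sequential" else kin.sim_switch
        return [(-1.0, off)]
    # Cd8a and Cd8b1 share windows
    if timing == "sequential":
        if branch == "CD4":
            return [(-1.0, kin.seq_cd8a_off)]
        return [(-1.0, kin.seq_cd8a_off), (kin.seq_cd4_off, 2.0)]
    if branch == "CD4":
        return [(-1.0, kin.sim_switch)]
    return always


def _coreceptor_on(t: float, windows: list[tuple[float, float]]) -> bool:
    return any(on <= t < off for on, off in windows)


def program_mean(
    true_time: np.ndarray,
    program: str,
    kin: Kinetics = Kinetics(),
    *,
    baseline: float = 1.0,
    branch: np.ndarray | None = None,
    gene_branch: str | None = None,
    activation_scale: float = 1.0,
    timing: str = "sequential",
    cd4_lineage_silenced: bool = False,
) -> np.ndarray:
    """Mean expression of a gene of the given program at the given times.

    Maturation programs are monotone logistic ramps pinned to ``baseline``
    at one end and ``baseline * fold`` at the other; the activation program
    is a Gaussian pulse equal to ``baseline`` at both ends and
    ``baseline * (1 + (A - 1) * activation_scale)`` at its centre; lineage
    programs are late sigmoids gated on the matching branch; coreceptor
    genes are products of steep logistic on/off windows.
    """
    t = np.asarray(true_time, dtype=float)
    if np.any((t < 0) | (t > 1)):
        raise ValueError("true_time must lie in [0, 1]")
    if program == "maturation_up":
        g = _ramp(t, kin.maturation_center, kin.maturation_steepness)
        return baseline * (1.0 + (kin.maturation_fold - 1.0) * g)
    if program == "maturation_down":
        g = _ramp(t, kin.maturation_center, kin.maturation_steepness)
        return baseline * (kin.maturation_fold - (kin.maturation_fold - 1.0) * g)
    if program == "activation_pulse":
        amp = (kin.activation_amplitude - 1.0) * activation_scale
        pulse = np.exp(
            -((t - kin.activation_center) ** 2) / (2.0 * kin.activation_width**2)
        )
        return baseline * (1.0 + amp * pulse)
    if program in ("cd4_lineage", "cd8_lineage"):
        if program == "cd4_lineage" and cd4_lineage_silenced:
            return np.full_like(t, baseline)
        want = "CD4" if program == "cd4_lineage" else "CD8"
        gate = np.ones_like(t)
        if program == "cd8_lineage" and cd4_lineage_silenced:
            # MHC class II-deficient regime: every cell is CD8-fated, so the
            # CD8 program is ungated regardless of the coreceptor path taken
            pass
        elif branch is not None:
            gate = (np.asarray(branch) == want).astype(float)
        elif gene_branch is not None:
            gate = float(gene_branch == want) * gate
        g = _sigmoid(kin.lineage_steepness * (t - kin.lineage_onset))
        return baseline * (1.0 + (kin.lineage_fold - 1.0) * g * gate)
    if program == "housekeeping":
        return np.full_like(t, baseline)
    if program == "coreceptor":
        if gene_branch is None or branch is None:
            raise ValueError("coreceptor kinetics need the gene name and cell branches")
        out = np.zeros_like(t)
        for br in ("CD4", "CD8"):
            sel = np.asarray(branch) == br
            if not np.any(sel):
                continue
            on = np.zeros(sel.sum())
            for t_on, t_off in coreceptor_windows(gene_branch, br, timing, kin):
                on = on + _window(t[sel], t_on, t_off, kin.coreceptor_steepness)
            out[sel] = kin.coreceptor_on_mean * np.clip(on, 0.0, 1.0)
        return out
    raise ValueError(f"unknown program {program!r}")


# ---------------------------------------------------------------------------
# dataset generation


def _stage_window(stage: int, kin: Kinetics) -> tuple[float, float]:
    width = 1.0 / _N_STAGES
    pad = kin.stage_overlap * width
    lo = max(0.0, stage * width - pad)
    hi = min(1.0, (stage + 1) * width + pad)
    return lo, hi


def _gene_table(config: SimulationConfig) -> pd.DataFrame:
    rows: list[tuple[str, str]] = [(g, "coreceptor") for g in CORECEPTOR_GENES]
    prefixes = {
        "maturation_up": "MUP",
        "maturation_down": "MDN",
        "activation_pulse": "ACT",
        "cd4_lineage": "LIN4",
        "cd8_lineage": "LIN8",
        "housekeeping": "HK",
    }
    for prog, prefix in prefixes.items():
        n = int(config.program_sizes.get(prog, 0))
        rows.extend((f"{prefix}{i:04d}", prog) for i in range(n))
    return pd.DataFrame(rows, columns=["gene_id", "program"])


def generate_dataset(
    config: SimulationConfig,
) -> tuple[CountMatrix, CellAnnotation, GroundTruth]:
    """Simulate one condition's count matrix with its ground truth.

    Reproducible: a fixed config (including seed) yields bit-identical
    counts. Cells are drawn phenotype by phenotype with latent times
    uniform in overlapping stage windows (pre-selection early,
    intermediates middle, SP late); each SP cell's branch matches its sort
    phenotype while earlier cells are assigned a branch 50/50.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    kin = config.kinetics

    cells = []
    for pheno in PHENOTYPES:
        n = config.cells_per_subset()[pheno]
        if n < 0:
            raise ValueError(f"negative cell count for {pheno}")
        lo, hi = _stage_window(_STAGE[pheno], kin)
        t = rng.uniform(lo, hi, size=n)
        if pheno == "CD4_SP":
            br = np.full(n, "CD4")
        elif pheno == "CD8_SP":
            br = np.full(n, "CD8")
        else:
            br = rng.choice(["CD4", "CD8"], size=n)
        for j in range(n):
            cells.append((pheno, float(t[j]), str(br[j])))
    if not cells:
        raise ValueError("no cells requested")
    phenotype = np.array([c[0] for c in cells])
    true_time = np.array([c[1] for c in cells])
    branch = np.array([c[2] for c in cells])
    n_cells = len(cells)

    genes = _gene_table(config)
    n_genes = len(genes)
    baselines = rng.lognormal(kin.baseline_log_mean, kin.baseline_log_sd, size=n_genes)

    means = np.empty((n_cells, n_genes), dtype=float)
    for j, (gene_id, prog) in enumerate(zip(genes["gene_id"], genes["program"])):
        means[:, j] = program_mean(
            true_time,
            prog,
            kin,
            baseline=1.0 if prog == "coreceptor" else baselines[j],
            branch=branch,
            gene_branch=gene_id if prog == "coreceptor" else (
                "CD4" if prog == "cd4_lineage" else "CD8" if prog == "cd8_lineage" else None
            ),
            activation_scale=config.activation_scale,
            timing=config.coreceptor_timing,
            cd4_lineage_silenced=config.cd4_lineage_silenced,
        )
    scale = config.library_size_mean / means.sum(axis=1).mean()
    means *= scale

    theta = config.nb_dispersion
    if theta > 1e8:  # near-Poisson limit
        counts = rng.poisson(means)
    else:
        p = theta / (theta + means)
        counts = rng.negative_binomial(theta, p)
    counts = counts.astype(np.int64)

    dropout = config._dropout_by_program()
    rate_per_gene = genes["program"].map(dropout).to_numpy(dtype=float)
    if np.any(rate_per_gene > 0):
        drop = rng.random(counts.shape) < rate_per_gene[None, :]
        counts[drop] = 0

    # latent coreceptor state from the on/off window logic
    true_state = np.empty(n_cells, dtype=object)
    for i in range(n_cells):
        cd4_on = _coreceptor_on(
            true_time[i], coreceptor_windows("Cd4", branch[i], config.coreceptor_timing, kin)
        )
        cd8a_on = _coreceptor_on(
            true_time[i], coreceptor_windows("Cd8a", branch[i], config.coreceptor_timing, kin)
        )
        true_state[i] = {
            (True, True): "DP_state",
            (True, False): "CD4_state",
            (False, True): "CD8_state",
            (False, False): "DN_state",
        }[(cd4_on, cd8a_on)]
    true_state = true_state.astype(str)

    cell_ids = [
        f"{config.condition}_{phenotype[i]}_{i:05d}" for i in range(n_cells)
    ]
    cm = CountMatrix(counts, cell_ids, list(genes["gene_id"]))
    ann = CellAnnotation(
        pd.DataFrame(
            {
                "cell_id": cell_ids,
                "phenotype": phenotype,
                "condition": config.condition,
                "batch": config.batch,
            }
        )
    )
    program_of_gene = pd.Series(
        genes["program"].to_numpy(), index=genes["gene_id"], name="program"
    )
    genesets = {
        "maturation": GeneSetRef(
            "maturation",
            frozenset(genes.loc[genes["program"].isin(
                ["maturation_up", "maturation_down"]), "gene_id"]),
        ),
        "activation": GeneSetRef(
            "activation",
            frozenset(genes.loc[genes["program"] == "activation_pulse", "gene_id"]),
        ),
        "lineage": GeneSetRef(
            "lineage",
            frozenset(genes.loc[genes["program"].isin(
                ["cd4_lineage", "cd8_lineage"]), "gene_id"]),
        ),
    }
    truth = GroundTruth(true_time, true_state, branch, program_of_gene, genesets)
    return cm, ann, truth


def export_truth_genesets(truth: GroundTruth, outdir: str | Path) -> dict[str, Path]:
    """Write the generator's truth gene sets as one-gene-per-line files.

    Refuses overlapping sets (the truth programs are disjoint by
    construction, so any overlap signals a corrupted GroundTruth).
    """
    sets = truth.truth_genesets
    names = list(sets)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            overlap = sets[a].genes & sets[b].genes
            if overlap:
                raise ValueError(
                    f"truth gene sets {a!r} and {b!r} overlap ({len(overlap)} genes)"
                )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, gs in sets.items():
        path = outdir / f"{name}.txt"
        write_gene_set(gs, path)
        paths[name] = path
    return paths
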