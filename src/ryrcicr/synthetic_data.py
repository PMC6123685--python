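"""Synthetic-data generators emulating the wet-lab inputs of the pipeline.

Every stage of the analysis can be exercised without instrument data: the
generators draw [3H]ryanodine binding curves forward from the biphasic model
with Gaussian replicate noise, single-site ryanodine saturation series for
Scatchard analysis, antiphase cytoplasmic/ER fluorescence traces with
calibration segments, and toy two-domain coordinate fixtures with known rigid
displacements.  All generators are seed-deterministic.

Default study conditions follow the emulated experiments: 4 replicates per
pCa point, Gaussian noise of SD 0.02 on the B/Bmax scale (the order of the
published SEM bars), a 12-point pCa grid from 8 to 3, and an ER calibration
floor at 7.655% of Fmax.  The genotype truth table in :func:`gen_paper_panel`
uses printed values where the study reports them (WT pCa50 4.79, F3713A
4.93, eightfold KA shifts for the disease mutants) and clearly tagged
illustrative values elsewhere.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .binding_fit import BindingCurve, SaturationSeries
from .model_core import BindingModelParams, activity
from .trace_analysis import ER_FMIN_FRACTION, Trace

DEFAULT_PCA_GRID = tuple(np.round(np.linspace(8.0, 3.0, 12), 4))
DEFAULT_NOISE_SD = 0.02
DEFAULT_REPLICATES = 4


@dataclass
class GeneratorConfig:
    """Replicate structure and noise level shared by the binding generators."""

    seed: int
    noise_sd: float = DEFAULT_NOISE_SD
    replicates: int = DEFAULT_REPLICATES
    pca_grid: tuple[float, ...] = DEFAULT_PCA_GRID

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def gen_binding_curve(
    truth: BindingModelParams,
    grid=DEFAULT_PCA_GRID,
    noise_sd: float = DEFAULT_NOISE_SD,
    replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
    genotype: str = "synthetic",
    condition: str = "control",
) -> BindingCurve:
    """Binding curve drawn forward from the biphasic model.

    B = A(truth, ca) + N(0, noise_sd) per replicate, truncated at zero
    (bound counts cannot be negative).  Identical seeds give identical
    tables.
    """
    rng = np.random.default_rng(seed)
    pca = np.asarray(grid, dtype=float)
    clean = activity(truth, 10.0 ** (-pca))
    noisy = clean[:, None] + rng.normal(0.0, noise_sd, size=(pca.size, replicates))
    noisy = np.maximum(noisy, 0.0)
    return BindingCurve.from_replicate_matrix(genotype, condition, pca, noisy)


def gen_saturation(
    Bmax: float,
    Kd_nM: float,
    grid_nM=(3.0, 5.0, 8.0, 12.0, 16.0, 20.0),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SaturationSeries:
    """Single-site saturation series B = Bmax*F/(F + Kd) with optional noise."""
    if not (Bmax > 0 and Kd_nM > 0):
        raise ValueError("Bmax and Kd must be > 0")
    rng = np.random.default_rng(seed)
    free = np.asarray(grid_nM, dtype=float)
    bound = Bmax * free / (free + Kd_nM)
    if noise_sd > 0:
        bound = np.maximum(bound + rng.normal(0.0, noise_sd, size=free.shape), 1e-12)
    return SaturationSeries(free_nM=free, bound=bound)


def gen_dual_trace(
    osc_per_min: float = 5.0,
    cyto_amplitude: float = 0.6,
    cyto_baseline: float = 0.05,
    er_upper: float = 0.8,
    er_lower: float = 0.55,
    duration_s: float = 180.0,
    sampling_hz: float = 10.0,
    caffeine_window: tuple[float, float] | None = (120.0, 150.0),
    caffeine_responsive: bool = True,
    Fmax_cyto: float = 1000.0,
    Fmax_er: float = 800.0,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> tuple[Trace, Trace]:
    """Antiphase cytoplasmic-spike / ER-sawtooth trace pair, in raw F units.

    Cytoplasmic release events are Gaussian-shaped spikes at regular
    intervals; each event steps the ER level down toward ``er_lower`` with
    linear refill toward ``er_upper`` between events.  A caffeine window
    either triggers a massive release (cyto surge, ER dump — wild-type-like)
    or does nothing (mutant-like).  Calibration segments realizing Fmin and
    Fmax for each channel are appended after the recording; the ER floor sits
    at 7.655% of Fmax by default.  Returned traces carry raw fluorescence
    with the matching Fmin/Fmax anchors and the caffeine event window.
    """
    if er_upper <= er_lower:
        raise ValueError("er_upper must exceed er_lower")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sampling_hz)) + 1
    t = np.arange(n) / sampling_hz

    cyto = np.full(n, cyto_baseline)
    er = np.full(n, er_upper)
    spike_width_s = 1.0
    if osc_per_min > 0:
        period = 60.0 / osc_per_min
        spike_times = np.arange(period, duration_s - 1.0, period)
    else:
        spike_times = np.array([])
    if caffeine_window is not None:
        c0, c1 = caffeine_window
        spike_times = spike_times[(spike_times < c0 - 2.0) | (spike_times > c1 + 5.0)]

    refill_rate = (er_upper - er_lower) / max(
        60.0 / osc_per_min if osc_per_min > 0 else duration_s, 1.0
    )
    level = er_upper
    last_t = 0.0
    for st in spike_times:
        cyto += cyto_amplitude * np.exp(-0.5 * ((t - st) / (spike_width_s / 2.355)) ** 2)
        # sawtooth: refill since last event, then step down at the event
        seg = (t >= last_t) & (t < st)
        er[seg] = np.minimum(level + refill_rate * (t[seg] - last_t), er_upper)
        level = min(level + refill_rate * (st - last_t), er_upper) - (er_upper - er_lower)
        last_t = st
    seg = t >= last_t
    er[seg] = np.minimum(level + refill_rate * (t[seg] - last_t), er_upper)

    if caffeine_window is not None and caffeine_responsive:
        c0, c1 = caffeine_window
        in_win = (t >= c0) & (t <= c1)
        cyto[in_win] = np.maximum(
            cyto[in_win],
            cyto_baseline
            + 1.4 * cyto_amplitude * np.exp(-(t[in_win] - c0) / 8.0),
        )
        er = np.where(in_win, 0.15 * er_upper, er)
        after = t > c1
        er[after] = np.minimum(
            0.15 * er_upper + refill_rate * (t[after] - c1), er_upper
        )

    cyto += rng.normal(0.0, noise_sd, size=n)
    er += rng.normal(0.0, noise_sd, size=n)

    # calibration segments: 5 s at Fmin, 5 s at Fmax (normalized 0 and 1)
    n_cal = int(round(5.0 * sampling_hz))
    t_cal = t[-1] + (np.arange(2 * n_cal) + 1) / sampling_hz
    cal = np.concatenate([np.zeros(n_cal), np.ones(n_cal)])
    time = np.concatenate([t, t_cal])
    cyto = np.concatenate([cyto, cal])
    er = np.concatenate([er, cal])

    fmin_er = ER_FMIN_FRACTION * Fmax_er
    raw_cyto = cyto * Fmax_cyto
    raw_er = fmin_er + er * (Fmax_er - fmin_er)
    events = (
        [{"label": "caffeine-10mM", "start_s": caffeine_window[0],
          "end_s": caffeine_window[1]}]
        if caffeine_window is not None
        else []
    )
    cyto_trace = Trace(time, raw_cyto, "cyto", Fmin=0.0, Fmax=Fmax_cyto,
                       events=list(events))
    er_trace = Trace(time, raw_er, "ER", Fmin=fmin_er, Fmax=Fmax_er,
                     events=list(events))
    return cyto_trace, er_trace


def gen_two_domain_fixture(
    out_dir: str | Path,
    shift=(2.0, 0.0, 0.0),
    n_atoms_per_domain: int = 30,
    seed: int = 0,
    formats: tuple[str, ...] = ("pdb", "cif"),
) -> dict[str, Path]:
    """Write a toy two-domain protein in two states with a known rigid shift.

    Domain A (residues 1..n) is identical between states; domain B (residues
    n+1..2n) is rigidly translated by ``shift`` angstroms in state B.  Both
    PDB and mmCIF renderings are written for each state; the returned dict
    maps e.g. "stateA.pdb" to its path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    n = n_atoms_per_domain
    coords_a = rng.uniform(0.0, 15.0, size=(n, 3))
    coords_b = rng.uniform(20.0, 35.0, size=(n, 3))  # separated blob
    shift = np.asarray(shift, dtype=float)

    def build(domain_b_offset: np.ndarray) -> gemmi.Structure:
        structure = gemmi.Structure()
        structure.name = "two-domain synthetic fixture"
        model = gemmi.Model("1")
        chain = gemmi.Chain("A")
        for i, xyz in enumerate(np.vstack([coords_a, coords_b + domain_b_offset])):
            residue = gemmi.Residue()
            residue.name = "ALA"
            residue.seqid = gemmi.SeqId(i + 1, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.occ = 1.0
            atom.b_iso = 20.0
            atom.pos = gemmi.Position(*xyz)
            residue.add_atom(atom)
            chain.add_residue(residue)
        model.add_chain(chain)
        structure.add_model(model)
        structure.setup_entities()
        return structure

    states = {"stateA": build(np.zeros(3)), "stateB": build(shift)}
    paths: dict[str, Path] = {}
    for state, structure in states.items():
        for fmt in formats:
            path = out_dir / f"{state}.{fmt}"
            if fmt == "pdb":
                structure.write_pdb(str(path))
            else:
                structure.make_mmcif_document().write_file(str(path))
            paths[f"{state}.{fmt}"] = path
    return paths


#: toy fixture domain ranges for n_atoms_per_domain = 30
TWO_DOMAIN_RANGES = {"A": (1, 30), "B": (31, 60)}


@dataclass
class GenotypeTruth:
    label: str
    control: BindingModelParams
    caffeine: BindingModelParams
    provenance: dict[str, str] = field(default_factory=dict)


def default_truth_table() -> list[GenotypeTruth]:
    """Genotype truth table for the emulated mutant panel.

    pCa50 values printed in the study text (WT 4.79, F3713A 4.93, eightfold
    KA shift for the C4192W-like disease mutant) are tagged "paper-printed";
    everything else (Amax, KI, caffeine-state pKA values, and the 10-fold
    I4925A-like shift taken from the study's qualitative statements) is
    tagged ILLUSTRATIVE and must never be asserted against published numbers.
    """
    ki = 1e-3
    wt = BindingModelParams.from_pk(Amax=0.4, pKA=4.79, pKI=3.0)
    table = [
        GenotypeTruth(
            "WT",
            control=wt,
            caffeine=wt.replace(KA=10.0 ** -5.8),
            provenance={"pKA_control": "paper-printed", "pKA_caffeine": "ILLUSTRATIVE",
                        "Amax": "ILLUSTRATIVE", "KI": "ILLUSTRATIVE"},
        ),
        GenotypeTruth(
            "W4644A-like",  # sensitized, caffeine-insensitive
            control=wt.replace(KA=10.0 ** -5.6),
            caffeine=wt.replace(KA=10.0 ** -5.6),
            provenance={"pKA_control": "ILLUSTRATIVE",
                        "caffeine_equals_control": "by-construction"},
        ),
        GenotypeTruth(
            "I4925A-like",  # ~10-fold sensitized, further sensitized by caffeine
            control=wt.replace(KA=10.0 ** -5.79),
            caffeine=wt.replace(KA=10.0 ** -6.79),
            provenance={"pKA_control": "ILLUSTRATIVE (10-fold vs WT)",
                        "pKA_caffeine": "ILLUSTRATIVE (further 10-fold)"},
        ),
        GenotypeTruth(
            "F3713A-like",
            control=wt.replace(KA=10.0 ** -4.93, Amax=0.25),
            caffeine=wt.replace(KA=10.0 ** -5.4, Amax=0.25),
            provenance={"pKA_control": "paper-printed",
                        "pKA_caffeine": "ILLUSTRATIVE", "Amax": "ILLUSTRATIVE"},
        ),
        GenotypeTruth(
            "C4192W-like",  # eightfold KA shift vs WT
            control=wt.replace(KA=wt.KA / 8.0),
            caffeine=wt.replace(KA=wt.KA / 80.0),
            provenance={"KA_ratio_control": "paper-printed (eightfold)",
                        "pKA_caffeine": "ILLUSTRATIVE"},
        ),
    ]
    assert abs(ki - wt.KI) < 1e-12
    return table


def gen_paper_panel(
    seed: int,
    config: GeneratorConfig | None = None,
    truth_table: list[GenotypeTruth] | None = None,
) -> dict[str, object]:
    """Full synthetic dataset: curves per genotype x condition, plus manifest.

    Returns {"curves": list[BindingCurve], "truths": list[GenotypeTruth],
    "manifest": dict}; the manifest records every truth value with its
    provenance tag so that round-trip tests can distinguish paper-printed
    values from illustrative ones.
    """
    cfg = config or GeneratorConfig(seed=seed)
    truths = truth_table if truth_table is not None else default_truth_table()
    seeds = np.random.SeedSequence(seed).generate_state(2 * len(truths)) % (2**31)
    curves: list[BindingCurve] = []
    manifest: dict[str, object] = {"seed": seed, "noise_sd": cfg.noise_sd,
                                   "replicates": cfg.replicates, "genotypes": {}}
    for i, truth in enumerate(truths):
        for j, (condition, params) in enumerate(
            [("control", truth.control), ("caffeine-10mM", truth.caffeine)]
        ):
            curves.append(
                gen_binding_curve(
                    params, cfg.pca_grid, cfg.noise_sd, cfg.replicates,
                    seed=int(seeds[2 * i + j]),
                    genotype=truth.label, condition=condition,
                )
            )
        manifest["genotypes"][truth.label] = {
            "control": json.loads(truth.control.to_json()),
            "caffeine": json.loads(truth.caffeine.to_json()),
            "provenance": truth.provenance,
        }
    return {"curves": curves, "truths": truths, "manifest": manifest}
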