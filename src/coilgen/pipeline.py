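"""End-to-end conformer-pool generation.

For each of ``n_structures`` output slots the pipeline repeats, up to
``tries_per_structure`` times: sample per-residue (phi, psi) from the
configured neighbor-dependent distributions, build the backbone, screen for
CA clashes (with an optional unknotting repair), run the optional
side-chain and minimization hooks, screen for all-atom overlaps, and write
the accepted conformer as ``<base>min_<k>.pdb``.  A ledger records every
trial and the reason each rejected one failed.

With a fixed seed and hooks disabled the whole run is deterministic: the
same configuration produces byte-identical PDB files.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np

from . import clash, ndrd, unknot
from .builder import BackboneGeometry, Conformation, DEFAULT_GEOMETRY, build_chain, write_ensemble_pdb
from .hooks import HookCommand, run_hook
from .ndrd import RamachandranGrid, ResidueKey
from .sampler import BiasSpec, Mode, ModeContext, assign_torsions, read_bias_file

REASON_CA = "CA clash"
REASON_UNKNOT = "unknot fail"
REASON_SIDECHAIN = "sidechain fail"
REASON_MINIMIZE = "minimization fail"
REASON_ATOM = "atom clash"


@dataclass
class RunConfig:
    """All knobs of a generation run; only `sequence` has no default."""

    sequence: str
    n_structures: int = 10
    mode: Mode = Mode.TRIPLET
    filename_base: str = "ens_"
    dataset: str = "TCBIG"
    tries_per_structure: int = 30
    sidechain_enabled: bool = False
    gromacs_enabled: bool = False
    keep_temp: bool = False
    unknot_delta: float = 30.0
    max_unknot_torsions: int = 0
    seed: Optional[int] = None
    bias_file: Optional[Union[str, Path]] = None
    ndrd_dir: Optional[Union[str, Path]] = None
    out_dir: Union[str, Path] = "."
    combined_ensemble: bool = False
    sidechain_command: Optional[HookCommand] = None
    minimize_command: Optional[HookCommand] = None
    geometry: BackboneGeometry = field(default_factory=BackboneGeometry)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence is required and must be nonempty")
        if self.n_structures < 1:
            raise ValueError("n_structures must be >= 1")
        if self.tries_per_structure < 1:
            raise ValueError("tries_per_structure must be >= 1")
        if isinstance(self.mode, str):
            self.mode = Mode(self.mode.upper())
        if self.mode.weighted and self.bias_file is None:
            raise ValueError(f"{self.mode.value} mode requires bias_file")


@dataclass
class TrialRecord:
    slot: int
    trial: int
    stage: str          # last stage reached
    accepted: bool
    reason: Optional[str] = None
    unknotted: bool = False


@dataclass
class RunLedger:
    """Per-trial accounting for one generation run."""

    n_structures: int
    tries_per_structure: int
    trials: list[TrialRecord] = field(default_factory=list)
    accepted_files: list[Path] = field(default_factory=list)

    @property
    def total_trials(self) -> int:
        return len(self.trials)

    @property
    def accepted(self) -> int:
        return sum(t.accepted for t in self.trials)

    @property
    def reasons(self) -> Counter:
        return Counter(t.reason for t in self.trials if t.reason is not None)

    def summary(self) -> str:
        lines = [
            f"accepted {self.accepted}/{self.n_structures} structures "
            f"in {self.total_trials} trials",
        ]
        for reason, count in sorted(self.reasons.items()):
            lines.append(f"  rejected ({reason}): {count}")
        return "\n".join(lines)


def _attempt(
    config: RunConfig,
    context: ModeContext,
    rng: np.random.Generator,
) -> tuple[Optional[Conformation], str, Optional[str], bool]:
    """One trial. Returns (conformation|None, stage, reason|None, unknotted)."""
    torsions = assign_torsions(config.sequence, context, rng)
    conf = build_chain(config.sequence, torsions, config.geometry)

    report = clash.find_ca_clashes(conf)
    unknotted = False
    if not report.clash_free:
        if config.max_unknot_torsions <= 0:
            return None, "ca_check", REASON_CA, False
        repaired = unknot.repair(
            conf, report, config.unknot_delta, config.max_unknot_torsions,
            config.geometry,
        )
        if repaired is None:
            return None, "unknot", REASON_UNKNOT, False
        conf, unknotted = repaired, True

    if config.sidechain_enabled:
        if config.sidechain_command is None:
            raise RuntimeError("side-chain hook enabled but no command configured")
        result = run_hook(conf, config.sidechain_command, keep_temp=config.keep_temp)
        if not result.success:
            return None, "sidechain", REASON_SIDECHAIN, unknotted
        conf = result.conformation

    if config.gromacs_enabled:
        if config.minimize_command is None:
            raise RuntimeError("minimization hook enabled but no command configured")
        result = run_hook(conf, config.minimize_command, keep_temp=config.keep_temp)
        if not result.success:
            return None, "minimize", REASON_MINIMIZE, unknotted
        conf = result.conformation

    if clash.find_atom_clashes(conf).atom_clashes:
        return None, "atom_check", REASON_ATOM, unknotted
    return conf, "accepted", None, unknotted


def generate_ensemble(
    config: RunConfig,
    grids: Optional[Mapping[ResidueKey, RamachandranGrid]] = None,
) -> RunLedger:
    """Run the full pipeline and write accepted conformers to disk.

    `grids` may be passed directly (e.g. from a synthetic fixture); otherwise
    they are loaded from ``config.ndrd_dir`` for the configured dataset.
    """
    if grids is None:
        if config.ndrd_dir is None:
            raise ValueError("either pass grids or set ndrd_dir in the config")
        grids = ndrd.load_dataset(config.ndrd_dir, config.dataset)

    biases: Optional[Mapping[int, BiasSpec]] = None
    if config.mode.weighted:
        biases = read_bias_file(config.bias_file)
        for idx in biases:
            if idx > len(config.sequence):
                raise ValueError(
                    f"bias residue index {idx} exceeds sequence length "
                    f"{len(config.sequence)}"
                )
    context = ModeContext(config.mode, grids, biases)

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    ledger = RunLedger(config.n_structures, config.tries_per_structure)
    accepted_confs: list[Conformation] = []
    for slot in range(1, config.n_structures + 1):
        for trial in range(1, config.tries_per_structure + 1):
            conf, stage, reason, unknotted = _attempt(config, context, rng)
            record = TrialRecord(
                slot, trial, stage, conf is not None, reason, unknotted
            )
            ledger.trials.append(record)
            if conf is not None:
                path = out_dir / f"{config.filename_base}min_{slot}.pdb"
                conf.write_pdb(path)
                ledger.accepted_files.append(path)
                accepted_confs.append(conf)
                break

    if config.combined_ensemble and accepted_confs:
        write_ensemble_pdb(
            accepted_confs, out_dir / f"{config.filename_base}ensemble.pdb"
        )
    return ledger
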