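"""Subprocess adapters for external side-chain packing and minimization tools.

The core pipeline never requires these: they are optional hook points that
write the current conformer to a temporary PDB file, invoke a user-supplied
command, and read the result back.  Command templates are plain argument
lists with ``{in}`` and ``{out}`` placeholders, e.g.::

    HookCommand(["scwrl4", "-i", "{in}", "-o", "{out}"])
    HookCommand(["my_minimizer", "{in}", "{out}"], log_success="Finished")

A nonzero exit status, a missing output file, or (when ``log_success`` is
set) a stdout/stderr log lacking the success marker all count as a failed
trial — never a crash of the run.
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from .builder import Conformation


class HookNotConfigured(RuntimeError):
    pass


@dataclass
class HookCommand:
    argv: list[str]
    log_success: Optional[str] = None   # substring the log must contain
    timeout: float = 600.0

    def render(self, infile: Path, outfile: Path) -> list[str]:
        return [
            arg.replace("{in}", str(infile)).replace("{out}", str(outfile))
            for arg in self.argv
        ]


@dataclass
class HookResult:
    conformation: Optional[Conformation]
    success: bool
    log: str = ""


def run_hook(
    conf: Conformation,
    command: HookCommand,
    workdir: Optional[Path] = None,
    keep_temp: bool = False,
) -> HookResult:
    """Write conf to PDB, run the command, parse the resulting PDB."""
    ctx = (
        tempfile.TemporaryDirectory()
        if workdir is None and not keep_temp
        else None
    )
    try:
        base = Path(ctx.name) if ctx is not None else Path(workdir or ".")
        base.mkdir(parents=True, exist_ok=True)
        infile = base / "hook_in.pdb"
        outfile = base / "hook_out.pdb"
        conf.write_pdb(infile)
        try:
            proc = subprocess.run(
                command.render(infile, outfile),
                capture_output=True,
                text=True,
                timeout=command.timeout,
            )
        except (OSError, subprocess.TimeoutExpired) as exc:
            return HookResult(None, False, log=str(exc))
        log = proc.stdout + proc.stderr
        if proc.returncode != 0 or not outfile.exists():
            return HookResult(None, False, log=log)
        if command.log_success is not None and command.log_success not in log:
            return HookResult(None, False, log=log)
        try:
            result = Conformation.from_pdb(outfile)
        except Exception as exc:  # unparsable tool output = failed trial
            return HookResult(None, False, log=f"{log}\n{exc}")
        return HookResult(result, True, log=log)
    finally:
        if ctx is not None:
            ctx.cleanup()
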