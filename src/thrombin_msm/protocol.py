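"""Bookkeeping for the published sampling-and-featurization protocol.

The production study design: ten targeted (TMD) runs between the E and E*
reference structures (five per direction), each 140 ns with frames stored
every 100 ps, are pooled and clustered into 100 seed conformations; each
seed spawns three continuation simulations (resolvated, resolvated with
sodium at physiological concentration, and solvent carried over), giving
300 seeded runs of 200 ns each — 200 without and 100 with Na+ — featurized
every 10 ps.  These numbers fix the frame counts every downstream stage
consumes; this module derives them from the design parameters so the
arithmetic is checkable.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["SeedingProtocol", "DEFAULT_PROTOCOL"]


@dataclass(frozen=True)
class SeedingProtocol:
    n_tmd_runs: int = 10
    tmd_length_ns: float = 140.0  # 100 ns ramp + 40 ns hold
    tmd_stride_ps: float = 100.0
    n_seed_clusters: int = 100
    restarts_per_seed: int = 3
    restarts_with_na: int = 1
    cmd_length_ns: float = 200.0
    cmd_stride_ps: float = 10.0

    @property
    def tmd_frames(self) -> int:
        """Pooled TMD frames entering the seeding clustering."""
        return round(self.n_tmd_runs * self.tmd_length_ns * 1000.0 / self.tmd_stride_ps)

    @property
    def n_cmd_runs(self) -> int:
        return self.n_seed_clusters * self.restarts_per_seed

    @property
    def n_cmd_with_na(self) -> int:
        return self.n_seed_clusters * self.restarts_with_na

    @property
    def n_cmd_without_na(self) -> int:
        return self.n_cmd_runs - self.n_cmd_with_na

    @property
    def frames_per_cmd(self) -> int:
        return round(self.cmd_length_ns * 1000.0 / self.cmd_stride_ps)

    @property
    def tica_frames_without_na(self) -> int:
        return self.n_cmd_without_na * self.frames_per_cmd

    @property
    def tica_frames_with_na(self) -> int:
        return self.n_cmd_with_na * self.frames_per_cmd


DEFAULT_PROTOCOL = SeedingProtocol()
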