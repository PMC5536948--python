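"""Validated configuration models for the simulator and analysis pipeline.

All physical quantities carry explicit units in their field descriptions:
lengths in micrometres (µm) unless the name says ``_px``, times in seconds
unless the name says ``_min``, angles in degrees measured counter-clockwise
from the +x axis in image coordinates (x rightward, y downward, origin at
the top-left pixel centre).
"""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

#: Channel roles understood by the simulator and the pipeline.
CHANNEL_ROLES = ("reference", "biosensor", "bem1", "cdc24", "whi5")

#: Event names whose offsets (minutes relative to bud emergence, <= 0) a
#: cell script may carry.  Defaults reflect typical population timing of
#: polarity-protein accumulation in G1: Whi5 leaves the nucleus ~25 min
#: before bud emergence, Bem1 and active-Cdc42 signal appear ~13 and
#: ~12 min before it, and optogenetically recruited GEF advances the
#: biosensor onset to ~27 min before bud emergence.
DEFAULT_EVENT_OFFSETS_MIN = {
    "whi5_exit": -25.0,
    "bem1_onset": -13.0,
    "biosensor_onset": -12.0,
    "biosensor_onset_recruited": -27.0,
}


class NoiseModel(BaseModel):
    """Camera noise: ``counts = offset + gain * Poisson(signal/gain) + N(0, read_sd)``.

    With this parameterization a flat region of mean photon signal ``m``
    (in count units above the offset) has variance ``gain * m + read_sd**2``.
    """

    model_config = ConfigDict(extra="forbid")

    enabled: bool = True
    background: float = Field(100.0, ge=0, description="constant camera offset, counts")
    gain: float = Field(2.0, gt=0, description="counts per detected photon")
    read_sd: float = Field(3.0, ge=0, description="Gaussian read-noise sd, counts")


class SimConfig(BaseModel):
    """Global parameters of a synthetic movie.

    The default pixel size of 0.162 µm/px makes a 100-pixel field span
    16.2 µm, the panel size used throughout the study this pipeline
    emulates.
    """

    model_config = ConfigDict(extra="forbid")

    pixel_size: float = Field(0.162, gt=0, description="µm per pixel")
    frame_interval: float = Field(30.0, gt=0, description="s between frames")
    duration: float = Field(3600.0, gt=0, description="movie length, s")
    field_size_px: int = Field(100, gt=0, description="square field side, px")
    cell_radius: float = Field(2.5, gt=0, description="default mother radius, µm")
    membrane_thickness: float = Field(
        0.25, gt=0, description="Gaussian sigma of the membrane annulus, µm"
    )
    channels: list[str] = Field(default=["reference", "biosensor"])
    ambient_level: float = Field(
        20.0, ge=0, description="uniform photon signal across the field, counts"
    )
    membrane_base_level: float = Field(
        40.0, ge=0, description="unpolarized membrane fluorescence, counts"
    )
    recruit_peak_level: float = Field(
        400.0, ge=0, description="membrane signal at a fully recruited site, counts"
    )
    noise: NoiseModel = Field(default_factory=NoiseModel)
    rng_seed: int = 0

    @field_validator("channels")
    @classmethod
    def _channels_valid(cls, v: list[str]) -> list[str]:
        if len(set(v)) != len(v):
            raise ValueError("channel roles must be unique")
        for role in v:
            if role not in CHANNEL_ROLES:
                raise ValueError(f"unknown channel role {role!r}; allowed: {CHANNEL_ROLES}")
        return v

    @property
    def n_frames(self) -> int:
        import math

        return int(math.floor(self.duration / self.frame_interval)) + 1

    @property
    def field_um(self) -> float:
        return self.field_size_px * self.pixel_size


class RecruitmentKinetics(BaseModel):
    """Photo-recruitment kinetics of the optogenetic LOVpep/ePDZ pair.

    A pulse drives membrane binding to its plateau within ``on_time``
    (modelled as a linear rise; the measured relocation is faster than
    10 s), after which the photo-excited state relaxes exponentially to
    the dark state with half-time ``dark_half_time`` (80 s).
    """

    model_config = ConfigDict(extra="forbid")

    on_time: float = Field(10.0, ge=0, description="rise time to plateau, s")
    dark_half_time: float = Field(80.0, gt=0, description="dark-state decay half-time, s")
    pulse_footprint_sigma: float = Field(
        0.5, gt=0, description="spatial sigma of an activation spot, µm"
    )


class PunctumSpec(BaseModel):
    """One scripted cortical punctum, placed by membrane angle."""

    model_config = ConfigDict(extra="forbid")

    channel: str
    angle_deg: float = Field(ge=0, lt=360)
    birth_s: float = 0.0
    death_s: float = Field(default=float("inf"))
    intensity: float = Field(200.0, gt=0, description="peak counts above membrane")
    partner: Optional[str] = Field(
        None, description="channel of a colocalized partner punctum, if any"
    )


class CellScript(BaseModel):
    """Ground-truth behaviour of one simulated mother cell.

    Event offsets are minutes relative to bud emergence and must be
    non-positive: polarity events precede budding.
    """

    model_config = ConfigDict(extra="forbid")

    center: tuple[float, float] = Field(description="mother centre, px (x, y)")
    radius: float = Field(2.5, gt=0, description="mother radius, µm")
    bud_emergence_time: Optional[float] = Field(
        None, description="s on the movie clock; None = never buds"
    )
    bud_site_angle: float = Field(0.0, ge=0, lt=360, description="degrees on the perimeter")
    bud_growth_rate: float = Field(
        2e-3, gt=0, description="bud radius growth, µm/s"
    )
    event_offsets: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_EVENT_OFFSETS_MIN)
    )
    responder: bool = True
    nuclear_radius: float = Field(0.9, gt=0, description="Whi5 nuclear disc radius, µm")
    puncta_script: list[PunctumSpec] = Field(default_factory=list)

    @field_validator("event_offsets")
    @classmethod
    def _offsets_nonpositive(cls, v: dict[str, float]) -> dict[str, float]:
        for name, off in v.items():
            if off > 0:
                raise ValueError(
                    f"event offset {name}={off} must be <= 0 (events precede bud emergence)"
                )
        return v

    def event_time(self, name: str) -> Optional[float]:
        """Absolute time (s) of a named event, or None if not applicable."""
        if self.bud_emergence_time is None or name not in self.event_offsets:
            return None
        return self.bud_emergence_time + self.event_offsets[name] * 60.0


class BiasModelConfig(BaseModel):
    """Configuration of the bud-site bias Monte Carlo.

    Responders polarize toward the target with a prescribed polarization
    efficiency (default 0.75, i.e. a bud-target angle of 22.5°).
    Non-responders bud at an angle drawn from a model distribution on
    ``nonresponder_range``: model1 has mean 90° (the fully random
    expectation), model2 mean 102° (the empirically measured aggregate
    bias), and ``uniform_circle`` draws target and bud independently and
    uniformly on the circle.
    """

    model_config = ConfigDict(extra="forbid")

    responder_fraction: float = Field(1.0, ge=0, le=1)
    responder_pe: float = Field(0.75, ge=-1, le=1)
    responder_jitter_deg: float = Field(0.0, ge=0, description="sd of angular noise")
    nonresponder_model: str = Field("model1", pattern="^(model1|model2|uniform_circle)$")
    nonresponder_range: tuple[float, float] = (46.0, 180.0)
    nonresponder_mean_angle: Optional[float] = Field(
        None, description="degrees; defaults to 90 (model1) or 102 (model2)"
    )
    n_cells: int = Field(50, ge=1)
    rng_seed: int = 0

    @model_validator(mode="after")
    def _fill_and_check(self) -> "BiasModelConfig":
        lo, hi = self.nonresponder_range
        if not (0.0 <= lo < hi <= 180.0):
            raise ValueError("nonresponder_range must satisfy 0 <= lo < hi <= 180")
        if self.nonresponder_mean_angle is None:
            object.__setattr__(
                self,
                "nonresponder_mean_angle",
                102.0 if self.nonresponder_model == "model2" else 90.0,
            )
        mean = self.nonresponder_mean_angle
        if self.nonresponder_model != "uniform_circle" and not (lo < mean < hi):
            raise ValueError(
                f"nonresponder_mean_angle {mean} must lie strictly inside the range {lo}-{hi}"
            )
        return self
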