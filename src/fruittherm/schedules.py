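"""Fruit-development schedules: property and size trajectories vs DAB.

The developmental clock is DAB (days after full bloom).  Four maturity
stages are distinguished: M1 (60 DAB, end of cell division), M2 (90 DAB,
cell expansion), M3 (120 DAB, green mature) and M4 (130 DAB, ripe).  A
schedule stores, per stage, tissue water contents and densities, per-side
surface conductance to water and shortwave reflectance, and the fruit
linear size relative to M1; values at intermediate DAB are linearly
interpolated.  Growth keeps fruit proportions constant, so one scalar
height factor scales all three semi-axes.

The built-in mango schedule is synthetic: stage-to-stage changes honour the
measured relative statements for cv. Cogshall (sunny-side conductance 19.3 %
below the shaded side at M2; reflectance rising 27.8 %/13.8 % on the
shaded/sunny side between M2 and M4; pulp density +5.6 % and stone density
-2.9 % over development with a +14.8 % stone excursion between M2 and M3;
conductivity and heat capacity falling by less than 20 %; height +46.13 %),
anchored to typical absolute values for a fleshy drupe.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .properties import (
    DEFAULT_CP_COEFFS,
    DEFAULT_K_COEFFS,
    SurfaceProperties,
    TissueProperties,
)

__all__ = ["Stage", "DevelopmentSchedule", "default_mango_schedule"]

TISSUES = ("pulp", "peel", "stone")
SIDES = ("sunny", "shaded")


@dataclass(frozen=True)
class Stage:
    """Interpolated snapshot of the schedule at one DAB."""

    dab: float
    size_scale: float  # linear scale relative to the first stage
    tissues: dict[str, TissueProperties]
    surfaces: dict[str, SurfaceProperties]


@dataclass
class DevelopmentSchedule:
    dab: np.ndarray
    size_scale: np.ndarray
    xw: dict[str, np.ndarray]  # per tissue
    sg: dict[str, np.ndarray]  # per tissue
    gw: dict[str, np.ndarray]  # per side
    a_sw: dict[str, np.ndarray]  # per side
    emissivity: float = 0.94
    k_coeffs: tuple[float, float] = DEFAULT_K_COEFFS
    cp_coeffs: tuple[float, float] = DEFAULT_CP_COEFFS

    def __post_init__(self) -> None:
        n = self.dab.size
        arrays = [self.size_scale, *self.xw.values(), *self.sg.values(),
                  *self.gw.values(), *self.a_sw.values()]
        if any(a.size != n for a in arrays):
            raise ValueError("schedule channels must share the DAB grid")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.dab[0]), float(self.dab[-1])

    def _interp(self, values: np.ndarray, dab: float) -> float:
        lo, hi = self.span
        if not lo <= dab <= hi:
            raise ValueError(f"DAB {dab} outside schedule span [{lo}, {hi}]")
        return float(np.interp(dab, self.dab, values))

    def at(self, dab: float) -> Stage:
        tissues = {
            t: TissueProperties.from_water_content(
                self._interp(self.xw[t], dab),
                self._interp(self.sg[t], dab),
                self.k_coeffs,
                self.cp_coeffs,
            )
            for t in TISSUES
        }
        surfaces = {
            s: SurfaceProperties(
                A_sw=self._interp(self.a_sw[s], dab),
                emissivity=self.emissivity,
                Gw=self._interp(self.gw[s], dab),
            )
            for s in SIDES
        }
        return Stage(
            dab=dab,
            size_scale=self._interp(self.size_scale, dab),
            tissues=tissues,
            surfaces=surfaces,
        )

    def fixed(self, channels: set[str]) -> "DevelopmentSchedule":
        """Copy with the given channels frozen at their first-stage value.

        Channels: ``size``, ``gw``, ``a_sw``, ``thermal`` (water content and
        density together, hence K, Cp and Sg).
        """
        unknown = channels - {"size", "gw", "a_sw", "thermal"}
        if unknown:
            raise ValueError(f"unknown channels: {sorted(unknown)}")

        def freeze(arr: np.ndarray) -> np.ndarray:
            return np.full_like(arr, arr[0])

        out = replace(self)
        if "size" in channels:
            out.size_scale = freeze(self.size_scale)
        if "gw" in channels:
            out.gw = {s: freeze(a) for s, a in self.gw.items()}
        if "a_sw" in channels:
            out.a_sw = {s: freeze(a) for s, a in self.a_sw.items()}
        if "thermal" in channels:
            out.xw = {t: freeze(a) for t, a in self.xw.items()}
            out.sg = {t: freeze(a) for t, a in self.sg.items()}
        return out

    # -- tidy CSV interface ----------------------------------------------
    def to_csv(self, path) -> None:
        rows = []
        for i, dab in enumerate(self.dab):
            for t in TISSUES:
                rows.append(
                    {
                        "DAB": dab,
                        "tissue": t,
                        "xw": self.xw[t][i],
                        "Sg": self.sg[t][i],
                        "Gw_sunny": self.gw["sunny"][i],
                        "Gw_shaded": self.gw["shaded"][i],
                        "A_sw_sunny": self.a_sw["sunny"][i],
                        "A_sw_shaded": self.a_sw["shaded"][i],
                        "size_scale": self.size_scale[i],
                    }
                )
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "DevelopmentSchedule":
        df = pd.read_csv(path)
        dab = np.sort(df["DAB"].unique().astype(float))
        by = {t: df[df["tissue"] == t].sort_values("DAB") for t in TISSUES}
        for t, sub in by.items():
            if sub.shape[0] != dab.size:
                raise ValueError(f"tissue {t!r} missing rows for some DAB")
        first = by["pulp"]
        return cls(
            dab=dab,
            size_scale=first["size_scale"].to_numpy(float),
            xw={t: by[t]["xw"].to_numpy(float) for t in TISSUES},
            sg={t: by[t]["Sg"].to_numpy(float) for t in TISSUES},
            gw={
                "sunny": first["Gw_sunny"].to_numpy(float),
                "shaded": first["Gw_shaded"].to_numpy(float),
            },
            a_sw={
                "sunny": first["A_sw_sunny"].to_numpy(float),
                "shaded": first["A_sw_shaded"].to_numpy(float),
            },
            **kwargs,
        )


def default_mango_schedule() -> DevelopmentSchedule:
    """Synthetic cv. Cogshall schedule over DAB 60-130 (stages M1-M4)."""
    return DevelopmentSchedule(
        dab=np.array([60.0, 90.0, 120.0, 130.0]),
        # height +46.13 % overall, nearly final by M3
        size_scale=np.array([1.0, 1.25, 1.42, 1.4613]),
        xw={
            "pulp": np.array([0.88, 0.87, 0.85, 0.84]),
            "peel": np.array([0.78, 0.76, 0.73, 0.72]),
            "stone": np.array([0.50, 0.47, 0.44, 0.42]),
        },
        sg={
            # pulp +5.6 % M1->M4; peel assumed equal to pulp
            "pulp": np.array([1000.0, 1020.0, 1040.0, 1056.0]),
            "peel": np.array([1000.0, 1020.0, 1040.0, 1056.0]),
            # stone: -8.0 % vs pulp at M2, +14.8 % M2->M3, -2.9 % overall
            "stone": np.array([980.0, 938.0, 1077.0, 951.0]),
        },
        gw={
            # sunny 19.3 % below shaded at M2; both declining M2->M4
            "sunny": np.array([5.4e-4, 4.84e-4, 4.6e-4, 4.4e-4]),
            "shaded": np.array([5.5e-4, 6.0e-4, 5.5e-4, 5.2e-4]),
        },
        a_sw={
            # +13.8 % (sunny) and +27.8 % (shaded) between M2 and M4
            "sunny": np.array([0.44, 0.42, 0.44, 0.478]),
            "shaded": np.array([0.44, 0.40, 0.46, 0.511]),
        },
    )
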