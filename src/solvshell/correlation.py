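"""Descriptor–flexibility correlation panels.

For each protein region and RMSF variant, regional flexibility ratios
(organic solvent vs water) are plotted against four solvent-mobility
descriptors — inverse bulk model viscosity, solvent mobility ratio,
surface retardation factor, and inverse local viscosity — and summarized
by the Pearson correlation coefficient across solvents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .viscosity import local_viscosity

__all__ = ["CorrelationPanel", "DESCRIPTORS", "pearson", "build_panels"]

DESCRIPTORS = (
    "inv_bulk_viscosity",
    "mobility_ratio",
    "retardation",
    "inv_local_viscosity",
)


@dataclass
class CorrelationPanel:
    region: str
    variant: str
    descriptor: str
    points: list[tuple[str, float, float]]     # (solvent, x, y)
    r: float | None
    n: int

    def __post_init__(self) -> None:
        if self.descriptor not in DESCRIPTORS:
            raise ValueError(f"unknown descriptor {self.descriptor!r}")
        if self.r is not None and not (-1.0 - 1e-12 <= self.r <= 1.0 + 1e-12):
            raise ValueError("r outside [-1, 1]")


def pearson(x, y) -> float:
    """Sample Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc * xc).sum())
    sy = np.sqrt((yc * yc).sum())
    if sx == 0 or sy == 0:
        raise ValueError("zero variance: correlation undefined")
    return float((xc * yc).sum() / (sx * sy))


def _descriptor_x(
    descriptor: str,
    solvent: str,
    region: str,
    solvent_props: pd.DataFrame,
    regional_D: pd.DataFrame,
    water: str,
) -> float:
    def prop(s, col):
        row = solvent_props.loc[solvent_props["solvent"] == s, col]
        if row.empty:
            raise KeyError(f"missing bulk property {col!r} for solvent {s!r}")
        return float(row.iloc[0])

    def dloc(s, rgn):
        row = regional_D.loc[
            (regional_D["solvent"] == s) & (regional_D["region"] == rgn),
            "D_local",
        ]
        if row.empty:
            raise KeyError(
                f"missing regional diffusion for ({s!r}, {rgn!r})"
            )
        return float(row.iloc[0])

    if descriptor == "inv_bulk_viscosity":
        return 1.0 / prop(solvent, "eta_model")
    if descriptor == "mobility_ratio":
        return dloc(solvent, region) / dloc(water, region)
    if descriptor == "retardation":
        return dloc(solvent, region) / prop(solvent, "D_bulk")
    if descriptor == "inv_local_viscosity":
        eta_loc = local_viscosity(
            prop(solvent, "eta_model"), prop(solvent, "D_bulk"),
            dloc(solvent, region),
        )
        return 1.0 / eta_loc
    raise ValueError(f"unknown descriptor {descriptor!r}")


def build_panels(
    flexibility: pd.DataFrame,
    solvent_props: pd.DataFrame,
    regional_D: pd.DataFrame,
    regions: list[str] | None = None,
    variants: list[str] | None = None,
    descriptors: tuple[str, ...] = DESCRIPTORS,
    include_water: bool = True,
    water: str = "water",
) -> list[CorrelationPanel]:
    """Assemble one panel per region x variant x descriptor.

    ``flexibility`` has columns (region, variant, solvent, ratio) with
    ratio the regional flexibility relative to water; ``solvent_props``
    has (solvent, eta_model, D_bulk); ``regional_D`` has
    (solvent, region, D_local).  With ``include_water`` the water point
    (x_water, 1) is added to every panel.  A missing (region, solvent)
    pair raises, naming the pair.
    """
    regions = regions or sorted(flexibility["region"].unique())
    variants = variants or sorted(flexibility["variant"].unique())
    panels = []
    for region in regions:
        for variant in variants:
            sub = flexibility[
                (flexibility["region"] == region)
                & (flexibility["variant"] == variant)
            ]
            solvents = [s for s in sub["solvent"] if s != water]
            for desc in descriptors:
                points = []
                for s in solvents:
                    row = sub[sub["solvent"] == s]
                    if row.empty:
                        raise KeyError(
                            f"missing flexibility for ({region!r}, {s!r})"
                        )
                    x = _descriptor_x(
                        desc, s, region, solvent_props, regional_D, water
                    )
                    points.append((s, x, float(row["ratio"].iloc[0])))
                if include_water:
                    xw = _descriptor_x(
                        desc, water, region, solvent_props, regional_D, water
                    )
                    points.append((water, xw, 1.0))
                xs = [p[1] for p in points]
                ys = [p[2] for p in points]
                r = pearson(xs, ys) if len(points) >= 3 else None
                panels.append(CorrelationPanel(
                    region=region, variant=variant, descriptor=desc,
                    points=points, r=r, n=len(points),
                ))
    return panels


def panels_to_frame(panels: list[CorrelationPanel]) -> pd.DataFrame:
    rows = []
    for p in panels:
        for solvent, x, y in p.points:
            rows.append({
                "region": p.region, "variant": p.variant,
                "descriptor": p.descriptor, "solvent": solvent,
                "x": x, "y": y, "r": p.r, "n": p.n,
            })
    return pd.DataFrame(rows)
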