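"""Incidence summaries and two-sample proportion tests.

Summarises the resolved catalogue as unique-locus counts per host class
and viral genus with per-genome ratios, and compares incidence between
host classes with the pooled two-proportion chi-square test (Yates
continuity correction on by default, matching the standard R
``prop.test`` behaviour).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Tuple

import pandas as pd
from scipy.stats import chi2


def two_proportion_test(
    x1: int, n1: int, x2: int, n2: int, continuity: bool = True
) -> Dict[str, float]:
    """Pooled two-sample proportion test (chi-square, 1 df, two-sided).

    With ``continuity`` the Yates correction subtracts
    ``0.5*(1/n1 + 1/n2)`` from ``|p1 - p2|`` (floored at zero) before
    squaring.  Without correction the statistic equals the square of
    the pooled two-proportion z statistic.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0:
            raise ValueError("sample sizes must be positive")
        if not 0 <= x <= n:
            raise ValueError(f"count {x} outside [0, {n}]")
    p1 = x1 / n1
    p2 = x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return {"chi2": 0.0, "p": 1.0}
    d = abs(p1 - p2)
    if continuity:
        d = max(0.0, d - 0.5 * (1.0 / n1 + 1.0 / n2))
    stat = d * d / (pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    return {"chi2": stat, "p": float(chi2.sf(stat, 1))}


def loci_summary(
    catalogue,
    host_class_map: Mapping[str, str],
    genomes_screened: Mapping[str, int],
) -> pd.DataFrame:
    """Unique-locus counts and per-genome ratios per (host class, genus).

    A locus (ortholog set) counts in every host class that contains at
    least one of its carrier species.  Ratios are exact quotients
    loci / genomes screened for the class.  A ``Totals`` row and a
    ``all`` class column-group complete the marginals.
    """
    sets = getattr(catalogue, "ortholog_sets", catalogue)
    for s in sets:
        for sp in (m.species for m in s.members):
            if sp not in host_class_map:
                raise KeyError(f"species not mapped to a host class: {sp}")
    classes = sorted(genomes_screened)
    genera = sorted({s.group for s in sets})
    counts: Dict[Tuple[str, str], int] = {}
    for s in sets:
        touched = {host_class_map[m.species] for m in s.members}
        for cls in touched:
            counts[(cls, s.group)] = counts.get((cls, s.group), 0) + 1
    rows = []
    for genus in genera + ["Totals"]:
        for cls in classes:
            if genus == "Totals":
                loci = sum(counts.get((cls, g), 0) for g in genera)
            else:
                loci = counts.get((cls, genus), 0)
            n = genomes_screened[cls]
            rows.append(
                {
                    "host_class": cls,
                    "genus": genus,
                    "loci": loci,
                    "genomes_screened": n,
                    "ratio": loci / n,
                }
            )
    return pd.DataFrame(
        rows, columns=["host_class", "genus", "loci", "genomes_screened", "ratio"]
    )
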