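"""Region-diagnostic marker screening.

A site is a candidate marker for region R when all of R's individuals
carry one allele and no individual from any other region carries it.
This is descriptive screening (no multiple-testing machinery), the way
biogeographic candidate markers are usually tabulated from small
plastome panels; regions represented by a single individual are flagged
``singleton-region`` rather than silently trusted.
"""

from __future__ import annotations

import pandas as pd

from .types import MarkerCall, VariantSite


def screen_region_diagnostic(
    sites: list[VariantSite],
    region_labels: dict[str, str],
    include_classes: frozenset = frozenset({"SNP", "InDel"}),
) -> list[MarkerCall]:
    """Screen sites for region-diagnostic alleles.

    ``region_labels`` maps every individual id to its sampling region;
    individuals absent from the mapping (e.g. the genus reference row)
    are ignored.  Sites with missing data across the labeled individuals
    are excluded.  Output order is (position, region) and is invariant
    to the input order of individuals and sites.
    """
    if not region_labels:
        raise ValueError("no labeled individuals: every region needs at least one")
    regions: dict[str, list[str]] = {}
    for ind, reg in region_labels.items():
        regions.setdefault(reg, []).append(ind)
    for reg, inds in regions.items():
        if not inds:
            raise ValueError(f"region {reg} has zero individuals")

    calls: list[MarkerCall] = []
    labeled = sorted(region_labels)
    n_total = len(labeled)
    for site in sorted(sites, key=lambda s: s.ref_position):
        if site.var_class not in include_classes or site.ambiguous:
            continue
        if any(ind not in site.alleles for ind in labeled):
            continue
        for reg in sorted(regions):
            inds = regions[reg]
            target_alleles = {site.alleles[i] for i in inds}
            if len(target_alleles) != 1:
                continue
            allele = target_alleles.pop()
            others = [i for i in labeled if region_labels[i] != reg]
            if any(site.alleles[i] == allele for i in others):
                continue
            calls.append(
                MarkerCall(
                    ref_position=site.ref_position,
                    var_class=site.var_class,
                    target_region=reg,
                    allele=allele,
                    n_target=len(inds),
                    n_other=n_total - len(inds),
                    support_class="robust" if len(inds) >= 2 else "singleton-region",
                )
            )
    return calls


def markers_to_frame(calls: list[MarkerCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                position=c.ref_position + 1,
                var_class=c.var_class,
                target_region=c.target_region,
                allele=c.allele,
                n_target=c.n_target,
                n_other=c.n_other,
                support_class=c.support_class,
                status=c.status,
            )
            for c in calls
        ]
    )


def marker_matrix(
    sites: list[VariantSite], calls: list[MarkerCall], region_labels: dict[str, str]
) -> pd.DataFrame:
    """Color-coded-matrix analogue: rows = variant sites, columns =
    individuals, with a ``diagnostic_for`` column flagging marker sites."""
    diag = {}
    for c in calls:
        diag.setdefault(c.ref_position, []).append(c.target_region)
    ids = sorted(region_labels)
    rows = []
    for s in sorted(sites, key=lambda x: x.ref_position):
        row = dict(
            position=s.ref_position + 1,
            var_class=s.var_class,
            diagnostic_for=",".join(sorted(diag.get(s.ref_position, []))),
        )
        for i in ids:
            row[f"{i} ({region_labels[i]})"] = s.alleles.get(i, ".")
        rows.append(row)
    return pd.DataFrame(rows)
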