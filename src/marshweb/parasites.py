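"""Parasite life cycles overlaid on a food web.

A :class:`ParasiteRecord` lists a parasite's life-cycle stages in order
(first intermediate host first, definitive host last).  Each stage has
a set of suitable host labels and a transmission mode describing how
the parasite reaches that stage's host: ``trophic`` (the stage's host
eats the previous stage's host), ``direct`` (penetration/contact) or
``vector``.  Free-living stages use the reserved pseudo-host label
``"environment"``, which is present in every web.

The viability rule: a parasite can complete its life cycle in a web
only if every stage has at least one suitable host present, and — under
the strict default — every trophic stage-to-stage transition is
supported by at least one observed consumer-resource link from a
next-stage host to a current-stage host.  Parasite records also feed
back into web construction: a parasite recovered from a predator whose
previous-stage host is present implies a feeding link, which
:func:`infer_trophic_links` adds (idempotently, never removing links).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .webio import FoodWeb

__all__ = [
    "ENVIRONMENT",
    "LifeStage",
    "ParasiteRecord",
    "filter_viable_parasites",
    "infer_trophic_links",
    "host_richness",
    "read_parasite_table",
    "write_parasite_table",
]

#: Reserved label for free-living stages (eggs, cercariae, ...): a
#: pseudo-host that is present in every web.
ENVIRONMENT = "environment"

_MODES = ("trophic", "direct", "vector")


@dataclass(frozen=True)
class LifeStage:
    hosts: frozenset
    transmission: str = "trophic"

    def __post_init__(self):
        object.__setattr__(self, "hosts", frozenset(self.hosts))
        if not self.hosts:
            raise ValueError("a life stage needs at least one suitable host")
        if self.transmission not in _MODES:
            raise ValueError(f"transmission must be one of {_MODES}")


@dataclass(frozen=True)
class ParasiteRecord:
    name: str
    stages: tuple[LifeStage, ...]
    source: str = "literature"  # or "empirical"

    def __post_init__(self):
        object.__setattr__(self, "stages", tuple(self.stages))
        if not self.stages:
            raise ValueError(f"parasite {self.name!r} has no stages")

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    def all_hosts(self) -> frozenset:
        out: set = set()
        for st in self.stages:
            out |= st.hosts
        return frozenset(out - {ENVIRONMENT})


def _present_hosts(stage: LifeStage, present: set) -> set:
    """Suitable hosts of a stage found in the web (environment always)."""
    if ENVIRONMENT in stage.hosts:
        return (stage.hosts & present) | {ENVIRONMENT}
    return stage.hosts & present


def _is_viable(web: FoodWeb, rec: ParasiteRecord, present: set,
               require_trophic_support: bool) -> bool:
    idx = {lbl: i for i, lbl in enumerate(web.labels)}
    stage_hosts = [_present_hosts(st, present) for st in rec.stages]
    if any(not h for h in stage_hosts):
        return False
    if not require_trophic_support:
        return True
    for s in range(1, rec.n_stages):
        if rec.stages[s].transmission != "trophic":
            continue
        prev = stage_hosts[s - 1] - {ENVIRONMENT}
        nxt = stage_hosts[s] - {ENVIRONMENT}
        if not prev or not nxt:
            continue  # a free-living side needs no feeding link
        supported = any(web.A[idx[p], idx[h]] == 1 for p in nxt for h in prev)
        if not supported:
            return False
    return True


def filter_viable_parasites(web: FoodWeb, records,
                            require_trophic_support: bool = True
                            ) -> list[ParasiteRecord]:
    """Parasites whose every life stage can be completed in this web.

    Host labels not found in the web are treated as absent (with a
    warning the first time an unknown label is seen).  With
    ``require_trophic_support=False`` the rule relaxes to stage-wise
    host presence only.
    """
    present = set(web.labels)
    unknown: set = set()
    for rec in records:
        unknown |= rec.all_hosts() - present
    if unknown:
        warnings.warn(
            f"{len(unknown)} host labels not in web {web.name!r}; "
            "treated as absent")
    return [rec for rec in records
            if _is_viable(web, rec, present, require_trophic_support)]


def infer_trophic_links(web: FoodWeb, records
                        ) -> tuple[FoodWeb, pd.DataFrame]:
    """Add feeding links implied by parasite life cycles.

    A parasite found in a next-stage host implies that host eats the
    previous-stage (intermediate) host: for every record whose stages
    all have suitable hosts present, and every trophic transition with
    hosts ``h`` (stage s) and ``p`` (stage s+1) both present, the link
    ``p eats h`` is set if absent.  Links are only ever added, and the
    operation is idempotent.  Returns the augmented web and a provenance
    table of the added links.
    """
    present = set(web.labels)
    idx = {lbl: i for i, lbl in enumerate(web.labels)}
    A = web.A.copy()
    prov = []
    for rec in records:
        stage_hosts = [_present_hosts(st, present) for st in rec.stages]
        if any(not h for h in stage_hosts):
            continue  # cycle cannot complete here; implies nothing
        for s in range(1, rec.n_stages):
            if rec.stages[s].transmission != "trophic":
                continue
            for p in sorted(stage_hosts[s] - {ENVIRONMENT}):
                for h in sorted(stage_hosts[s - 1] - {ENVIRONMENT}):
                    if A[idx[p], idx[h]] == 0:
                        A[idx[p], idx[h]] = 1
                        prov.append({"web": web.name, "consumer": p,
                                     "resource": h, "parasite": rec.name,
                                     "provenance": "parasite-inferred"})
    out = FoodWeb(web.labels, A, web.category, web.name)
    return out, pd.DataFrame(prov, columns=["web", "consumer", "resource",
                                            "parasite", "provenance"])


def host_richness(web: FoodWeb, viable_records) -> pd.DataFrame:
    """Within-host parasite richness: the number of viable parasites that
    list the species as a suitable host at any life stage.

    The viability filter must already have been applied.  A parasite
    using a host at two stages counts once.  Every web species appears
    in the table; hosts of no parasite get richness 0.
    """
    users: dict[str, set] = {lbl: set() for lbl in web.labels}
    for rec in viable_records:
        for lbl in rec.all_hosts():
            if lbl in users:
                users[lbl].add(rec.name)
    rows = [{"web": web.name, "host": lbl,
             "richness": len(users[lbl]),
             "parasites": ";".join(sorted(users[lbl]))}
            for lbl in web.labels]
    return pd.DataFrame(rows)


# -- table IO ---------------------------------------------------------------

def write_parasite_table(records, path) -> None:
    """One CSV row per (parasite, stage): parasite, stage_index (1-based),
    transmission, hosts (semicolon-separated), source."""
    rows = []
    for rec in records:
        for s, st in enumerate(rec.stages, start=1):
            rows.append({"parasite": rec.name, "stage_index": s,
                         "transmission": st.transmission,
                         "hosts": ";".join(sorted(st.hosts)),
                         "source": rec.source})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_parasite_table(path) -> list[ParasiteRecord]:
    df = pd.read_csv(path, dtype={"parasite": str, "stage_index": int,
                                  "transmission": str, "hosts": str,
                                  "source": str})
    records = []
    for name, sub in df.groupby("parasite", sort=False):
        sub = sub.sort_values("stage_index")
        expected = list(range(1, len(sub) + 1))
        if sub["stage_index"].tolist() != expected:
            raise ValueError(
                f"parasite {name!r}: stage indices must be 1..{len(sub)}")
        stages = tuple(
            LifeStage(hosts=frozenset(h for h in row.hosts.split(";") if h),
                      transmission=row.transmission)
            for row in sub.itertuples())
        source = sub["source"].iloc[0] if "source" in sub else "literature"
        records.append(ParasiteRecord(name=name, stages=stages, source=source))
    return records
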