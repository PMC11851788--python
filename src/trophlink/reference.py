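"""Published functional-group isotope summaries for the Beibu Gulf food web.

These are the per-group sample sizes, mean ± SD δ13C and δ15N values and
trophic levels from an August 2022 bottom-trawl survey of the Beibu Gulf
(northwestern South China Sea), where 139 trophic species were classified
into 17 functional groups. The raw per-individual data are not public, so
this summary table is the package's reference input: it parameterises the
benchmark mixing problems (diet of benthic suspension feeders, copepods and
macro-zooplankton) and the trophic-level consistency checks.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import SourceSummary, TefModel
from .mixing import MixingProblem

# group, n, d13c_mean, d13c_sd, d15n_mean, d15n_sd, tl_mean, tl_sd, producer
_ROWS = [
    ("macroalgae", 6, -15.39, 1.00, 8.26, 1.01, 1.00, 0.00, True),
    ("som", 14, -20.94, 2.14, 3.21, 0.14, 1.00, 0.00, True),
    ("phytoplankton", 4, -19.64, 0.93, 5.62, 0.57, 1.00, 0.00, True),
    ("pom", 12, -20.67, 2.71, 3.58, 0.94, 1.00, 0.00, True),
    ("copepods", 14, -20.29, 0.81, 9.69, 1.88, 2.17, 0.55, False),
    ("macro_zooplankton", 30, -19.70, 1.41, 9.41, 1.41, 2.09, 0.42, False),
    ("benthic_suspension_feeder", 29, -16.89, 1.23, 9.87, 0.64, 2.22, 0.19, False),
    ("deposit_feeder", 10, -17.82, 1.19, 11.16, 1.75, 2.60, 0.51, False),
    ("benthic_decapoda_omnivores", 12, -17.60, 0.78, 11.52, 1.39, 2.71, 0.41, False),
    ("benthic_decapoda_predators", 80, -17.05, 1.17, 12.72, 1.43, 3.06, 0.42, False),
    ("benthic_stomatopoda_predators", 25, -17.29, 0.81, 12.85, 1.23, 3.10, 0.36, False),
    ("planktivorous_fish", 84, -17.76, 0.71, 13.72, 1.49, 3.35, 0.44, False),
    ("benthivorous_fish", 203, -17.42, 1.17, 13.59, 1.36, 3.31, 0.40, False),
    ("benthivorous_piscivorous_fish", 302, -17.45, 1.10, 13.46, 1.46, 3.28, 0.43, False),
    ("planktivorous_piscivorous_fish", 199, -17.90, 1.00, 13.75, 1.64, 3.36, 0.48, False),
    ("piscivorous_fish", 266, -17.13, 0.89, 14.74, 1.08, 3.65, 0.32, False),
    ("cephalopoda", 29, -17.96, 0.93, 14.10, 1.26, 3.47, 0.37, False),
]

FUNCTIONAL_GROUPS = pd.DataFrame(
    _ROWS,
    columns=[
        "group",
        "n",
        "d13c_mean",
        "d13c_sd",
        "d15n_mean",
        "d15n_sd",
        "tl_mean",
        "tl_sd",
        "producer",
    ],
).set_index("group")


def consumer_groups() -> pd.DataFrame:
    """The 13 consumer rows (trophic level above the producer baseline)."""
    return FUNCTIONAL_GROUPS[~FUNCTIONAL_GROUPS["producer"]]


def reference_source(group: str, tef: TefModel, consumer_d15n_mean: float, consumer_d15n_sd: float) -> SourceSummary:
    """A functional group viewed as a diet source for a given consumer.

    The nitrogen TEF follows the consumer (proportional enrichment evaluated
    at the consumer's δ15N; its SD propagates the consumer's δ15N spread).
    """
    row = FUNCTIONAL_GROUPS.loc[group]
    tef_mu, tef_sd = tef.for_consumer(consumer_d15n_mean, consumer_d15n_sd)
    return SourceSummary(
        label=group,
        mu=np.array([row["d13c_mean"], row["d15n_mean"]]),
        sd=np.array([row["d13c_sd"], row["d15n_sd"]]),
        tef_mu=tef_mu,
        tef_sd=tef_sd,
    )


#: benchmark mixing problems built entirely from the published summaries:
#: consumer group, its sources, and the source whose reported posterior-mean
#: diet share the survey's mixing analysis highlighted.
BENCHMARKS = {
    "benthic_suspension_feeder": {
        "consumer": "benthic_suspension_feeder",
        "sources": ["som", "pom", "phytoplankton"],
        "focus_source": "phytoplankton",
        "reported_mean": 0.90,
    },
    "copepods": {
        "consumer": "copepods",
        "sources": ["pom", "phytoplankton"],
        "focus_source": "phytoplankton",
        "reported_mean": 0.70,
    },
    "macro_zooplankton": {
        "consumer": "macro_zooplankton",
        "sources": ["pom", "phytoplankton", "copepods"],
        "focus_source": "pom",
        "reported_mean": 0.39,
    },
}


def build_benchmark(name: str, seed: int, residual_error: bool = True) -> tuple[MixingProblem, dict]:
    """Materialise a benchmark problem from the published summaries.

    Consumers are simulated as independent Normal draws with the group's
    printed mean/SD per isotope (sample size = the printed N); sources carry
    the printed means/SDs with carbon TEF 1.0 ± 0.4 ‰ and the proportional
    nitrogen TEF evaluated at the consumer group's mean δ15N.
    """
    if name not in BENCHMARKS:
        raise KeyError(f"unknown benchmark {name!r}; choose from {sorted(BENCHMARKS)}")
    spec = BENCHMARKS[name]
    row = FUNCTIONAL_GROUPS.loc[spec["consumer"]]
    tef = TefModel()
    sources = [
        reference_source(s, tef, row["d15n_mean"], row["d15n_sd"]) for s in spec["sources"]
    ]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = int(row["n"])
    consumers = np.column_stack(
        [
            rng.normal(row["d13c_mean"], row["d13c_sd"], size=n),
            rng.normal(row["d15n_mean"], row["d15n_sd"], size=n),
        ]
    )
    problem = MixingProblem(consumers=consumers, sources=sources, residual_error=residual_error)
    meta = {
        "consumer": spec["consumer"],
        "n": n,
        "focus_source": spec["focus_source"],
        "reported_mean": spec["reported_mean"],
    }
    return problem, meta
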