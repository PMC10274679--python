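"""Shared fixtures: modification spaces, tiny datasets, the default benchmark.

The default benchmark (50 proteins, 2000 spectra, seed 42) and its SS_MO /
SS_H-II search results are session-scoped because the SS_H-II search over
~1.3M peptidoforms takes a few minutes; every test that needs them shares
one computation.
"""

from dataclasses import dataclass

import pytest

from fpopseek.cli_report import builtin_workflow
from fpopseek.fdr_control import group_fdr_filter
from fpopseek.mod_model import (
    Modification,
    ModificationSpace,
    OXIDATION_MASS,
    ZERO_OFFSET,
)
from fpopseek.search_engine import search_dataset
from fpopseek.synthetic_data import evaluate_recovery, generate_benchmark


@pytest.fixture(scope="session")
def metox() -> Modification:
    return Modification("Met-ox", OXIDATION_MASS, frozenset("M"))


@pytest.fixture(scope="session")
def dioxidation_offset() -> Modification:
    return Modification(
        "Dioxidation", 2 * OXIDATION_MASS, frozenset("CFMWY"), mod_class="offset"
    )


@pytest.fixture(scope="session")
def hybrid_space(metox, dioxidation_offset) -> ModificationSpace:
    """Met-ox variable + dioxidation offset: the smallest hybrid space."""
    return ModificationSpace(
        variable=(metox,),
        offsets=(ZERO_OFFSET, dioxidation_offset),
        max_var_mods=3,
    )


@dataclass
class BenchmarkRun:
    bench: object          # synthetic_data.BenchmarkData
    results: dict          # workflow name -> (psms, filtered, report, recovery)


@pytest.fixture(scope="session")
def tiny_benchmark():
    """A fast end-to-end dataset: 10 proteins, 120 spectra."""
    return generate_benchmark(
        n_proteins=10, mean_length=200, n_spectra=120, seed=7
    )


@pytest.fixture(scope="session")
def default_benchmark():
    """The default ground-truthed benchmark searched with SS_MO and SS_H-II."""
    bench = generate_benchmark(
        n_proteins=50, mean_length=300, n_spectra=2000, seed=42
    )
    results = {}
    for name in ("SS_MO", "SS_H-II"):
        cfg = builtin_workflow(name)
        psms = search_dataset(bench.spectra, bench.peptides, cfg.space, cfg.search_params)
        filtered, report = group_fdr_filter(psms, cfg.assigned_mods, cfg.psm_fdr)
        recovery = evaluate_recovery(filtered, bench.truth)
        results[name] = {
            "psms": psms,
            "filtered": filtered,
            "report": report,
            "recovery": recovery,
        }
    return BenchmarkRun(bench=bench, results=results)
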