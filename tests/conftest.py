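"""Shared fixtures: small hand-built reports and two full-scale synthetic
reporting databases (a null one and one with a planted signal) reused by the
calibration and acceptance tests."""

from __future__ import annotations

from datetime import date

import numpy as np
import pytest

import pvsignal as pv
from pvsignal.synthetic import PTSpec, default_pt_catalog

# study-scale conditions, fixed once: a 100k-report universe with 2% focal
# drug prevalence over 400 null preferred terms with background reporting
# rates log-spaced on 0.004-0.04
NULL_SEED = 20260928
PLANTED_SEED = 11
PLANTED_PT = "PT9999"


def make_report(
    case_id: str = "C1",
    report_date: date = date(2023, 1, 15),
    drugs=(("focaldrug", pv.DrugRole.PRIMARY_SUSPECT, date(2023, 1, 1)),),
    events=(("PT0001", date(2023, 1, 10)),),
    **kwargs,
) -> pv.ICSRReport:
    return pv.ICSRReport(
        case_id=case_id,
        report_date=report_date,
        drugs=[pv.DrugEntry(n, r, s) for n, r, s in drugs],
        events=[pv.EventEntry(p, o) for p, o in events],
        **kwargs,
    )


@pytest.fixture(scope="session")
def null_database():
    """Raw synthetic reports with every risk ratio at 1 (no true signal)."""
    socs = [
        "Cardiac disorders",
        "Investigations",
        "Renal and urinary disorders",
        "Vascular disorders",
    ]
    rates = np.geomspace(0.004, 0.04, 400)
    catalog = [
        PTSpec(f"NPT{i:04d}", socs[i % 4], float(rates[i])) for i in range(400)
    ]
    config = pv.SyntheticConfig(
        n_reports=100_000, pt_catalog=catalog, seed=NULL_SEED
    )
    reports, truth = pv.generate_reports(config)
    return config, reports, truth


@pytest.fixture(scope="session")
def null_scan(null_database):
    """PT-level scan of the all-null database under default settings."""
    config, reports, _ = null_database
    analysis = pv.filter_by_drug_role(
        pv.deduplicate_reports(reports), config.drug_name
    )
    return pv.run_signal_scan(
        analysis, config.drug_name, level="pt", meddra_map=config.meddra_map()
    )


@pytest.fixture(scope="session")
def planted_database():
    """Synthetic reports with one planted PT at reporting risk ratio 5
    (background rate 0.01) among 30 null terms."""
    catalog = default_pt_catalog() + [
        PTSpec(PLANTED_PT, "Cardiac disorders", 0.01)
    ]
    config = pv.SyntheticConfig(
        n_reports=100_000,
        pt_catalog=catalog,
        planted_signals={PLANTED_PT: 5.0},
        seed=PLANTED_SEED,
    )
    reports, truth = pv.generate_reports(config)
    return config, reports, truth


@pytest.fixture(scope="session")
def planted_scan(planted_database):
    config, reports, _ = planted_database
    analysis = pv.filter_by_drug_role(
        pv.deduplicate_reports(reports), config.drug_name
    )
    return pv.run_signal_scan(
        analysis, config.drug_name, level="pt", meddra_map=config.meddra_map()
    )
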