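import pytest

from tirscan import align_trim, domain_scan, jc_classify, synthetic_data


@pytest.fixture(scope="session")
def panel_and_consensus():
    return synthetic_data.default_panel(1)


@pytest.fixture(scope="session")
def panel(panel_and_consensus):
    return panel_and_consensus[0]


@pytest.fixture(scope="session")
def consensus(panel_and_consensus):
    return panel_and_consensus[1]


@pytest.fixture(scope="session")
def profile(panel_and_consensus):
    panel, consensus = panel_and_consensus
    return synthetic_data.default_profile(panel, consensus)


@pytest.fixture(scope="session")
def planted_catalog(panel, profile):
    """200 proteins with one planted, 20%-diverged domain each."""
    return synthetic_data.plant_domains(
        200, panel, sub_fraction=0.2, master_seed=3
    )


@pytest.fixture(scope="session")
def annotated(panel, profile, planted_catalog):
    """Full scan -> trim -> classify run over the planted catalog."""
    catalog, truth = planted_catalog
    hits = domain_scan.search_profile(catalog, profile)
    hits = domain_scan.apply_inclusion(hits, profile)
    hits = domain_scan.dedup_overlaps(hits)
    hits = domain_scan.name_domains(hits)
    by_id = {p.id: p for p in catalog}
    extracted = {
        h.domain_id: domain_scan.extract_domain(h, by_id[h.protein_id], flank=0)
        for h in hits
    }
    rows = align_trim.map_many(extracted, profile)
    report = align_trim.gap_filter(rows)
    results = jc_classify.classify_many(report.kept, panel)
    return {"hits": hits, "rows": rows, "report": report, "results": results, "truth": truth}
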