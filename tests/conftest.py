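import pytest

from scaldnet import PlantedSignal, autoscale, build_response, filter_genes, generate_dataset

SMALL_SIGNALS = [
    PlantedSignal(
        name="ctol",
        kind="biphasic_early",
        onset_day=14,
        peak_day=61,
        amplitude=3.0,
        treatment_multipliers={"control": 1.0, "DPA": 0.15, "MCP": 0.1},
        gene_clusters={"ctol_cluster": 20},
        metabolite_ids=("CTOL", "farnesene_oxide_1", "farnesene_oxide_2"),
    ),
    PlantedSignal(
        name="methanol",
        kind="sigmoidal_late",
        onset_day=61,
        amplitude=3.0,
        treatment_multipliers={"control": 1.0, "DPA": 0.05, "MCP": 0.0},
        gene_clusters={"pme_cluster": 25},
        metabolite_ids=("methanol", "methyl_acetate", "methyl_hexanoate"),
    ),
    PlantedSignal(
        name="ripening",
        kind="monotone_ripening",
        amplitude=2.0,
        treatment_multipliers={"control": 1.0, "DPA": 0.9, "MCP": 0.35},
        gene_clusters={"ripening_cluster": 15},
        metabolite_ids=("alpha_farnesene", "hexyl_acetate"),
    ),
]


def small_dataset(seed=11, n_genes=300, n_metabolites=40, noise_sd=0.25):
    return generate_dataset(
        n_genes=n_genes,
        n_metabolites=n_metabolites,
        signals=SMALL_SIGNALS,
        noise_sd=noise_sd,
        seed=seed,
    )


@pytest.fixture(scope="session")
def planted():
    """A small planted dataset: (expression, metabolites, meta, annotation, truth)."""
    return small_dataset()


@pytest.fixture(scope="session")
def scaled(planted):
    """Autoscaled blocks + response for the small planted dataset."""
    expr, metab, meta, _, _ = planted
    expr_f, _ = filter_genes(expr, meta)
    return autoscale(expr_f), autoscale(metab), build_response(meta), meta
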