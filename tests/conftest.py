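"""Shared synthetic datasets; generated once per session."""

import numpy as np
import pytest

import imlineage as il


@pytest.fixture(scope="session")
def rna_planted():
    """Moderate RNA dataset with 5+3+4 planted QC violations.

    baseline_mean is raised so un-planted cells sit safely above the
    500-transcript floor at this reduced gene count.
    """
    cfg = il.RnaSimConfig(
        n_cells_per_type={
            "basal": 300,
            "lumL1": 300,
            "lumL2": 200,
            "intermediate": 150,
            "nonepithelial": 150,
        },
        n_genes=1200,
        baseline_mean=2.0,
        planted_bad_cells={"low_count": 5, "high_count": 3, "high_mito": 4},
        seed=11,
    )
    return il.generate_rna(cfg)


@pytest.fixture(scope="session")
def rna_filtered(rna_planted):
    filtered, report = il.filter_cells_rna(
        rna_planted.matrix, rna_planted.truth.gene_sets["mito"]
    )
    return filtered, report


@pytest.fixture(scope="session")
def rna_norm(rna_filtered):
    return il.normalize_log(rna_filtered[0])


@pytest.fixture(scope="session")
def atac_planted():
    """Moderate ATAC dataset with 4+3+2 planted QC violations."""
    cfg = il.AtacSimConfig(
        n_cells_per_type={"basal": 150, "luminal": 200, "intermediate": 150},
        n_peaks=1200,
        peak_mean=1.5,
        planted_bad_cells={"low_tss": 4, "low_fragments": 3, "high_reads": 2},
        seed=5,
    )
    return il.generate_atac(cfg)


@pytest.fixture(scope="session")
def atac_backgrounds(atac_planted):
    return il.sample_background_peaks(atac_planted.peaks, seed=17)


@pytest.fixture(scope="session")
def atac_homogeneous():
    """No type-specific peak programs: cells exchangeable given depth."""
    cfg = il.AtacSimConfig(
        n_cells_per_type={"basal": 150, "luminal": 200, "intermediate": 150},
        n_peaks=1200,
        peak_mean=1.5,
        frac_type_specific=0.0,
        seed=23,
    )
    return il.generate_atac(cfg)
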