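"""Shared fixtures: a default simulated screen and the corrected pipeline run."""

import numpy as np
import pandas as pd
import pytest

import crispy.simulate as sim
from crispy import benchmark, foldchange, gpr_correction


@pytest.fixture(scope="session")
def default_config():
    return sim.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def dataset(default_config):
    """Default simulated genome + screen (seed 1)."""
    return sim.simulate_dataset(default_config)


@pytest.fixture(scope="session")
def pipeline(dataset, default_config):
    """Full pipeline run on the default fixture: fold changes, GP fit, correction."""
    genome, screen = dataset
    filtered = foldchange.filter_low_plasmid(screen.counts)
    norm = foldchange.size_factor_normalize(filtered)
    guide_fc = foldchange.log2_foldchange(norm, screen.counts.plasmid_id, 1.0)
    # replicate-averaged guide fold changes for the single simulated cell line
    fc = guide_fc.fc.mean(axis=1)
    result = gpr_correction.run_sample(
        fc, genome.library, genome.segments, sample=default_config.cell_line
    )
    gene_original = foldchange.gene_level(
        foldchange.FoldChangeTable("guide", guide_fc.fc), genome.library
    ).fc.mean(axis=1)
    gene_corrected = result.gene_table.set_index("gene")["corrected_fc"]
    return {
        "genome": genome,
        "screen": screen,
        "config": default_config,
        "guide_fc": fc,
        "result": result,
        "gene_original": gene_original,
        "gene_corrected": gene_corrected.loc[gene_original.index],
    }


@pytest.fixture
def toy_segments_tsv(tmp_path):
    def _write(rows, name="segments.tsv"):
        path = tmp_path / name
        lines = ["chrom\tstart\tend\tcopy_number"]
        lines += ["\t".join(str(v) for v in r) for r in rows]
        path.write_text("\n".join(lines) + "\n")
        return str(path)

    return _write


def brute_force_aurc(fc: pd.Series, gene_set) -> float:
    """Independent AURC oracle: Riemann sum of the recall step function."""
    order = sorted(fc.index, key=lambda g: (fc[g], g))
    members = set(gene_set) & set(fc.index)
    total = len(members)
    hits = 0
    recall_sum = 0.0
    for g in order:
        if g in members:
            hits += 1
        recall_sum += hits / total
    return recall_sum / len(order)


def per_base_cn_oracle(segments, chrom, start, end):
    """Independent per-base oracle for size-weighted copy number."""
    values = []
    for b in range(start, end):
        for s in segments:
            if s.chrom == chrom and s.start <= b < s.end:
                values.append(s.copy_number)
                break
    if not values:
        return None, 0
    return float(np.mean(values)), len(values)
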