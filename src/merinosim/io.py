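"""Plain-text input/output: PLINK export, pedigree tables, manifests."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["write_plink", "write_pedigree", "write_trace", "write_manifest"]


def write_plink(population, ids, prefix) -> None:
    """Export genotypes in PLINK .ped/.map text dialect.

    Alleles are coded 1/2; ids are written 1-based with 0 for unknown
    parents.  The .map file reports chromosome, marker name, genetic
    position (cM) and a surrogate bp position.
    """
    prefix = Path(prefix)
    genome = population.genome
    ids = np.asarray(ids)
    haps = population.haplotypes(ids) + 1  # alleles 1/2
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for k, i in enumerate(ids):
            sex = 1 if population.sex[i] == 0 else 2
            sire = population.sire[i] + 1
            dam = population.dam[i] + 1
            pairs = np.empty(2 * genome.n_markers, dtype=np.uint8)
            pairs[0::2] = haps[k, 0]
            pairs[1::2] = haps[k, 1]
            fh.write(f"1 {i + 1} {max(sire, 0)} {max(dam, 0)} {sex} -9 "
                     + " ".join(map(str, pairs)) + "\n")
    with open(prefix.with_suffix(".map"), "w") as fh:
        idx = 0
        for c, pos in enumerate(genome.positions, start=1):
            for p in pos:
                fh.write(f"{c} snp{idx} {100 * p:.6f} {int(1e6 * p) + 1}\n")
                idx += 1


def write_pedigree(population, path, ids=None) -> None:
    """Four-column pedigree text: id, sire, dam, sex (+ birth cycle).

    Ids are 1-based; 0 marks an unknown parent.
    """
    if ids is None:
        ids = np.arange(population.n)
    ids = np.asarray(ids)
    df = pd.DataFrame({
        "id": ids + 1,
        "sire": np.maximum(population.sire[ids] + 1, 0),
        "dam": np.maximum(population.dam[ids] + 1, 0),
        "sex": np.where(population.sex[ids] == 0, "M", "F"),
        "birth_cycle": population.birth_cycle[ids],
    })
    df.to_csv(path, sep="\t", index=False)


def write_trace(trace: pd.DataFrame, path) -> None:
    trace.to_csv(path, index=False, float_format="%.10g")


def write_manifest(config, base_seed, path) -> None:
    """Record config, seed and package version next to the outputs."""
    import yaml

    from . import __version__

    with open(path, "w") as fh:
        yaml.safe_dump({"package": "merinosim", "version": __version__,
                        "base_seed": int(base_seed),
                        "config": config.to_dict()}, fh, sort_keys=False)
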