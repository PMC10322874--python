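#!/usr/bin/env python
"""Profile transporter classes and label uptake strategies per taxon.

Reads results/fixtures/bundled/, classifies transporter genes by KO into the
five sugar-transport classes (ABC, PTS, MFS, TonB, SusC) and scores each
taxon against the sharer / scavenger / selfish typology, using each taxon's
secreted fraction of CAZyme RPKM. The generator plants the three archetypes
in taxa 1-3, so those labels should be recovered.
"""

from pathlib import Path

import glyconiche as gn
from glyconiche.io_tables import TransporterKOMap, read_gene_table, read_sample_metadata
from glyconiche.transporters import classify_transporters, strategy_table

BASE = Path(__file__).resolve().parent.parent / "results"
FIX = BASE / "fixtures" / "bundled"
OUT = BASE / "transporters"
SAMPLE = "ST01SF"


def main() -> None:
    samples = read_sample_metadata(FIX / "metadata.tsv")
    genes = read_gene_table(FIX / "genes.tsv", samples)
    OUT.mkdir(parents=True, exist_ok=True)

    report = classify_transporters(genes, TransporterKOMap.default(), "genus", SAMPLE, samples)
    pm = gn.build_profile_matrix(genes, samples, SAMPLE)
    sec = gn.build_profile_matrix(genes, samples, SAMPLE, secreted_only=True)
    sec_frac = {
        t: float(sec.data.loc[t].sum() / pm.data.loc[t].sum())
        if t in sec.data.index and pm.data.loc[t].sum() > 0
        else 0.0
        for t in pm.taxa
    }
    tbl = strategy_table(report, sec_frac)
    tbl.to_csv(OUT / "strategies.tsv", sep="\t")
    print(f"labelling rule: {tbl.attrs['rule']}")
    print(tbl[["f_ABC", "f_specific", "f_SusC", "secreted_cazyme_fraction", "label"]].round(3))
    if report.n_genes_unmapped:
        print(f"unmapped transporter KOs: {dict(report.unmapped_kos)}")


if __name__ == "__main__":
    main()
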