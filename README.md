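# tmcontact

Interhelical residue-contact (IHRC) prediction for α-helical transmembrane
proteins. The package builds four sequence-derived, TMP-specific features —
evolutionary conservation (from a PSSM), evolutionary covariation (ELSC, MI
or OMES on a multiple sequence alignment, z-scored per protein), digitised
predicted topology, and the residue relative-position rank — assembles them
into a 31-element pair vector with two sliding windows of size 5, and
classifies each interhelical candidate pair with a small 1-D convolutional
network (five conv/ReLU/max-pool blocks of 512/1024/512/1024/1024 channels,
implemented directly on NumPy).

Ground-truth labels can be derived from PDB coordinates under three contact
definitions (heavy-atom < 5.5 Å; van der Waals radii + 0.6 Å; Cβ–Cβ ≤ 8 Å),
and a synthetic-data module generates alignments with planted coevolving
column pairs plus idealised helix-bundle coordinates whose geometric
contacts coincide with the planted couplings, so the whole pipeline is
testable offline.

## Layout

| module | role |
| --- | --- |
| `tmcontact.seqio` | FASTA / aligned FASTA / PSI-BLAST ASCII PSSM / PDB readers, prediction output files (pair list TSV + upper-triangular matrix) |
| `tmcontact.covariation` | ELSC / MI / OMES column-pair scores, z-score standardisation, TSV export/ingest |
| `tmcontact.features` | topology parsing, (E, T, R) tracks, candidate-pair enumeration, 31-element pair vectors |
| `tmcontact.labeling` | contact definitions I/II/III, van der Waals radius table, contact-map labeling |
| `tmcontact.model` | NumPy CNN, class-weighted training, prediction, metrics (ACC/Precision/Recall/MCC), protein-level k-fold splits, checkpoints |
| `tmcontact.synthetic` | seeded generators for MSAs, helix bundles and complete training sets |
| `tmcontact.pipeline` | per-protein prediction, cross-validation, controlled covariation-method comparison |
| `tmcontact.cli` | `tmcontact` command-line interface |

## CLI

```sh
# write synthetic fixtures (FASTA, aligned FASTA, PSSM, topology, PDB)
tmcontact simulate --outdir sim --seed 1

# train on the synthetic dataset and save a checkpoint
tmcontact train --n-proteins 40 --method elsc --seed 1 --out model.npz

# predict contacts for one protein (two output files, mutually consistent)
tmcontact predict --fasta sim/prot0.fasta --msa sim/prot0.aln.fasta \
    --pssm sim/prot0.pssm --topology sim/prot0.topo \
    --model model.npz --method elsc --out-prefix prot0

# protein-level five-fold cross-validation / covariation-method comparison
tmcontact cv --n-proteins 10 -k 5 --seed 1
tmcontact compare-cov --n-proteins 10 --methods elsc,mi,omes --seed 1
```

Topology strings use `H` for membrane-spanning residues and `i`/`o` for
inside/outside loops. Output pair lists and matrix files are 1-based.

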