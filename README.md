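# combind

Random-forest prediction of **joint transcription-factor-pair binding
sites** in short DNA reads.

Transcription factors (TFs) often bind DNA cooperatively as pairs, on a
composite site whose orientation (which factor comes first along the
strand) and spacing (gap or overlap between the two motifs) vary from pair
to pair — and sometimes within a pair.  Position weight matrices (PWMs)
assume one fixed configuration and independent positions, which limits
their accuracy for such flexible joint sites.  This package implements two
random-forest models trained on pairwise-selection (CAP-SELEX-style)
sequencing libraries:

- **JointRF** — uses a known composite (pairwise) PWM to select each
  read's most likely binding window, then trains a random forest on the
  window's nucleotides as positional features.  Scoring takes the maximum
  forest probability over all windows of both strands.
- **ComBind** — needs no composite motif.  The two individual-TF PWMs are
  extended with uniform `(0.25, 0.25, 0.25, 0.25)ᵀ` columns to 25
  positions (TF1 right-extended / TF2 left-extended for orientation
  TF1-TF2, mirrored for TF2-TF1), each read's best 25-nt window is chosen
  per orientation, and one forest is trained per orientation.  The final
  score is the average of the two orientation-specific max-per-position
  forest probabilities, covering all binding configurations in a single
  score.

Around the models, the package ships the complete experimental protocol:
dinucleotide-count-preserving shuffled negatives (Euler-path
construction), class-balanced 75/25 splits with a 25% pre-training subset,
a 4×5 hyperparameter grid search (minimum node size × fraction of
variables per split), N-padded log-odds PWM baseline scoring, AUROC and
paired Wilcoxon signed-rank comparison, OOB-based motif visualization, and
a planted-dimer read simulator with recorded ground truth.

Intended users: computational biologists modeling cooperative TF-DNA
binding from in-vitro selection data, and anyone needing a clean reference
implementation of the selection/training/evaluation protocol.

## Worked example

Simulate a library of 2,000 positive 40-nt reads carrying a planted
two-motif site (gap uniform on 0–10, all four orientations), build
shuffled negatives, run the full protocol, and compare the three models:

```python
from pathlib import Path
from combind.cli import run_experiment

table = run_experiment({
    "seed": 7,
    "simulation": {"n": 2000, "gap_min": 0, "gap_max": 10},
    "forest": {"n_trees": 200},
    "grid_search": True,
    "models": ["combind", "jointrf", "pwm"],
}, Path("demo"))
print(table)
```

Output (log lines abridged):

```
split: 3000 train / 1000 test / 750 pretrain (seed 7)
grid search chose min_node_size=5 mtry_fraction=0.30
            auroc
model
combind  0.972584
jointrf  0.959460
pwm      0.812596
```

The held-out AUROC is the probability that a random positive read
outscores a random shuffled negative.  ComBind, which models all spacings
and orientations at once, separates the classes almost perfectly; JointRF,
locked to one fixed-gap composite motif, trails slightly; the log-odds PWM
baseline with the same composite motif is clearly weaker on
variable-spacing data — the qualitative ordering ComBind > JointRF > PWM.
`demo/` receives the serialized models, per-read score TSVs, the grid
table and the AUROC table.

The same pipeline is available from the shell:

```bash
combind simulate --n 2000 --seed 7 --out-dir demo-data
combind run config.json --out-dir demo      # config as in the dict above
combind --help                              # shuffle / train / score / evaluate
```

Real libraries can be supplied as FASTA/FASTQ/plain-text reads
(`"reads": "library.fasta"` in the config) with PWM files in JASPAR,
MEME-minimal, or plain 4-row format.

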