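# okrfd

Replication fork directionality (RFD) analysis of strand-specific
Okazaki-fragment sequencing (OK-seq and related assays such as TrAEL-seq,
GLOE-seq or eSPAN) for genomicists studying the DNA replication program:
where replication initiates, where converging forks terminate, and where
long stretches of the genome are replicated by unidirectional forks — the
loci most exposed to head-on transcription–replication conflicts.

## The method

Okazaki fragments are synthesized on the lagging strand, so fragments
sequenced from the Crick strand come from rightward-moving forks and
fragments from the Watson strand from leftward-moving forks. With per-bin
read counts C and W (1 kb bins for mammalian genomes, 50 bp for yeast):

```
RFD = (C − W) / (C + W)        ∈ [−1, +1]
```

+1 means purely rightward-moving forks, −1 purely leftward, 0 equal
proportions. The pipeline:

1. **Counting** — fragments from a coordinate-sorted indexed BAM are
   assigned to fixed bins by their 5′-most coordinate and split by strand
   (`okrfd count`).
2. **RFD profiling** — raw per-bin RFD plus a smoothed track computed as
   the ratio of counts summed over 15 kb sliding windows stepped by one
   bin (`okrfd rfd`).
3. **HMM segmentation** — the step signal ΔRFDₙ = (RFDₙ₊₁ − RFDₙ)/2 is
   discretized into five genome-wide quantiles (windows with < 30 reads
   masked) and decoded with a fixed 4-state HMM: **Up** (initiation
   zones, ascending RFD), **Down** (termination zones, descending RFD)
   and two **Flat** states. Each zone gets an efficiency
   ΔRFD_segment = (RFD_end − RFD_start)/2 from 5 kb flanking windows — for
   an initiation zone this estimates its firing efficiency — and a
   confidence from the posterior state probabilities (`okrfd hmm`).
4. **Origin efficiency metric** — at each bin boundary, the Watson
   fraction of the left quadrant minus that of the right quadrant,
   `OEM = W_L/(W_L+C_L) − W_R/(W_R+C_R)`, computed over a ladder of
   quadrant widths (1 kb – 1 Mb) to expose RFD transitions at every scale
   (`okrfd oem`).
5. **Metagene profiles** — signal matrices and mean ± SE profiles of any
   RFD/OEM track around anchors (zone centers, TSS/TTS) or across scaled
   gene bodies (`okrfd metagene`).

A simulator (`okrfd simulate`) generates replication programs with known
origin positions and firing efficiencies, their analytic RFD, sampled
stranded read counts and optional synthetic BAMs, so the whole pipeline
can be exercised and calibrated without external data.

## Worked example

```python
import numpy as np, okrfd as ok

genome = ok.GenomeBinning({"chr1": 2_000_000}, 1000)
program = ok.make_program(5, genome, (0.5, 1.0), seed=11, transition_half_width=15_000)
truth = ok.true_rfd(program)
counts = ok.sample_counts(truth, 40, seed=12)

zones, track = ok.call_zones(counts)
for s in zones.by_state("Up"):
    print(f"[{s.start:>9,}, {s.end:>9,})  efficiency = {s.efficiency:.2f}  confidence = {s.confidence:.2f}")
```

prints

```
[   58,000,   100,000)  efficiency = 0.94  confidence = 0.96
[  289,000,   323,000)  efficiency = 0.49  confidence = 0.98
[  382,000,   421,000)  efficiency = 0.57  confidence = 0.96
[1,037,000, 1,078,000)  efficiency = 0.94  confidence = 0.99
[1,275,000, 1,323,000)  efficiency = 0.83  confidence = 0.92
```

The five planted origins sat at 78,771 / 308,569 / 401,474 / 1,058,772 /
1,292,547 bp with firing efficiencies 0.96 / 0.54 / 0.56 / 0.97 / 0.81:
every called initiation zone covers its origin and the measured
ΔRFD_segment tracks the planted efficiency to within a few hundredths.
The same dataset's strongest 30 kb-scale OEM peak falls at the 75 kb bin
boundary, next to the most efficient origin:

```python
oem = ok.compute_oem(counts, 30)
print(int(np.nanargmax(oem.values["chr1"])), round(float(np.nanmax(oem.values["chr1"])), 2))
# 75  0.72
```

The equivalent shell pipeline on a BAM is

```
okrfd run --bam okseq.bam --chrom-sizes genome.sizes --out results/sample
```

which writes Watson/Crick bedGraphs, raw and smoothed RFD tracks, IZ/TZ/
flat BEDs with efficiency and confidence in a TSV, high-|RFD| region
calls, multi-scale OEM tracks and a JSON manifest per stage.

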