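# External validation on the archived bundle photographs

The package's automated tests validate the workflow on synthetic bundles
only. The real winter-wheat bundle photographs that the method was
developed on are archived on Zenodo (DOI `10.5281/zenodo.14446564`,
~hundreds of images, two per bundle). Validating against them requires a
download of several gigabytes and, for the adjusted counts, replaying human
correction sessions — so this is a manual recipe, deliberately not part of
the test suite or any CI gate.

## Recipe

1. Download and unpack the Zenodo record into `data/real/`. Name images
   `<bundle_id>_<side>.png` (sides `top` and `bottom`).
2. Detect with the reference parameter set used for the published bundle
   figures:

   ```sh
   for img in data/real/*.png; do
     tillercount detect "$img" \
       --p1 95 --p2 30 --dmin 50 --rmin 20 --rmax 54 \
       --out "${img%.png}.detections.csv"
   done
   ```

   Note that `p1`/`p2` here act on this package's Sobel-magnitude edge
   threshold and raw accumulator votes; they are *not* numerically
   interchangeable with other Hough implementations, so expect to retune
   them (start from the values above and inspect overlays).
3. Correct each image by writing a session log (JSON `add`/`remove` events,
   see `tillercount correct --help`) while inspecting the overlay, or replay
   previously recorded session logs if you have them.
4. Aggregate the counts CSVs and evaluate against hand counts
   (`bundle_id,side,ground_truth`):

   ```sh
   tillercount evaluate counts.csv hand_counts.csv --patch-area 0.5 --out report.json
   ```

On the original photographs the semi-automatic workflow (automatic
detection plus manual correction) reached a correlation with disassembled
hand counts of R ≈ 0.97 and an RMSRE below 5 %; purely automatic counts are
substantially worse (RMSRE ≈ 10 %). Numbers in that range indicate a
successful reproduction; they cannot be asserted automatically because the
correction step is human.
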