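# Converting the public motor-imagery dataset

The pipeline was designed around the geometry of the large public
motor-imagery EEG dataset of Kaya et al. (*Scientific Data* 5:180211,
2018): 19 scalp channels, 1000 Hz recordings, five-finger movement
imageries plus a passive no-mental-task paradigm. The dataset ships as
MATLAB `.mat` containers, which are out of this package's core scope;
this note records the conversion recipe.

Each `.mat` file holds a struct `o` with (at least):

* `o.data` — samples × channels signal matrix (microvolts),
* `o.marker` — per-sample event code (1–5 for thumb..pinkie in the
  five-finger paradigm; 0 between tasks; 90s codes for service events),
* `o.sampFreq` — sampling rate,
* `o.chnames` — channel labels.

Recipe:

1. Load with `scipy.io.loadmat(path, squeeze_me=True,
   struct_as_record=False)` and take `o = mat["o"]`.
2. Find epoch onsets as the samples where `o.marker` transitions from 0
   to a task code; the action cue lasts 1 s, so each epoch is the
   half-open window `[onset, onset + sampFreq)`.
3. For the five-finger files, keep codes 1–5 as labels 1–5. For the
   no-mental-task files, cut non-overlapping 1 s windows and label them 6.
4. Balance to 100 epochs per class per subject (take the first 100 of
   each), stack into a trials × channels × samples array, and write it
   with `itdeeg.io.write_epoch_container` together with the sampling
   rate, labels, subject ids and channel names — or build a TSV event
   table (`onset_sample`, `label`) and export EDF, after which
   `itdeeg.io.read_edf_epochs` ingests it directly.

The hardware chain already applied a 0.53–100 Hz band-pass and a 50 Hz
notch to the 1000 Hz recordings, so no additional filtering is needed
before feature extraction.
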