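# The DVJTRIAL TSV dialect

A plain-text, tab-separated container for one motion-capture trial
(markers + force plates).  It exists so the whole pipeline — including its
test fixtures — can run on human-readable files; the binary C3D container
is supported separately (optional `ezc3d` dependency) for interoperability
with capture systems.

## Conventions

* **Units**: marker positions mm, forces N, moments N·mm, mass kg,
  height cm, rates Hz.
* **Lab frame**: X anterior (the direction the subject faces), Y to the
  subject's left, Z up; right-handed.  Declared in the header rather than
  assumed.
* **Force-plate moments** are expressed about the lab origin, which lies
  on the floor plane (Z = 0).  The center of pressure follows as
  `x = -My/Fz`, `y = Mx/Fz` wherever `Fz` is above the stance threshold.
* **Frames** are 0-based; intervals are half-open `[start, end)`.
* **Missing samples** are explicit: each marker has a validity column
  (`1`/`0`); masked coordinates are written as `nan`, never as zeros.
* Floats are written with `repr()` (shortest round-tripping form), so a
  write/read cycle reproduces the in-memory trial exactly, bit for bit.

## Layout

```
#DVJTRIAL	1                       magic + format version
#site	A
#trial_index	2
#static	0                        1 for the neutral-standing calibration trial
#marker_rate	240.0
#force_rate	1200.0               integer multiple of marker_rate
#subject_id	S01
#subject_mass_kg	62.3
#subject_height_cm	169.3
#axes	X-anterior Y-left Z-up
#units	markers=mm forces=N moments=N.mm
#moment_reference	lab-origin-floor
#n_plates	2
#MARKERS	frame	C7_x	C7_y	C7_z	C7_v	STRN_x	...
0	-60.2	0.0	1455.1	1	...
1	...
#FORCES	frame	p1_Fx	p1_Fy	p1_Fz	p1_Mx	p1_My	p1_Mz	p2_Fx	...
0	0.0	0.0	0.0	0.0	0.0	0.0	...
```

The `#MARKERS` block has one row per marker frame: the frame index, then
four columns (`_x`, `_y`, `_z`, `_v`) per marker in header order.  The
`#FORCES` block has one row per force sample with six channels per plate
(force then moment).  Force row `j` is simultaneous with marker row
`j // (force_rate / marker_rate)`.
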