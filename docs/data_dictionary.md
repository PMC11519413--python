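# Cohort CSV data dictionary

One row per stained slide; excluded biopsies (never sectioned) appear as a
single row with `excluded=True` and all measurements empty.  Missing values
are empty fields.  Units are abstract ("area units", "length units"): the
generator models relative variability, not absolute physical scale.

| column | type | description |
| --- | --- | --- |
| donor_id | string | deceased donor identifier |
| kidney_id | string | kidney identifier (`<donor>-L/R`) |
| biopsy_id | string | biopsy identifier (`<kidney>-<technique>-<replicate>`) |
| technique | string | retrieval technique: punch, core, or wedge |
| stain | string | H&E or PAS; empty on excluded biopsies |
| excluded | bool | biopsy removed after pathologist review (tissue folds, incomplete specimen) |
| medulla_present | bool | slide contains medulla; cortex area is then unavailable |
| cortex_area | float | delineated cortex area (area units); empty when medulla present |
| biopsy_depth | float | biopsy depth (length units) |
| biopsy_width | float | biopsy width (length units) |
| glomeruli_total | float | total glomeruli counted on the slide |
| glomeruli_sclerotic | float | sclerotic glomeruli counted on the slide |
| artery_count | float | arteries counted on the slide |
| arteriole_count | float | arterioles counted on the slide |
| vessel_count | float | arteries + arterioles |
| if_area | float | interstitial fibrosis area (area units) |
| ta_area | float | tubular atrophy area (area units) |
| artery_wall_thickness | float | wall thickness of the worst artery (length units) |
| artery_lumen_diameter | float | lumen diameter of the worst artery (length units) |
| artery_full_diameter | float | full diameter of the worst artery (length units) |
| artery_puncture | bool | worst artery punctured by the biopsy needle |

## Columns appended by `derive`

| column | description |
| --- | --- |
| healthy_glomeruli | glomeruli_total − glomeruli_sclerotic |
| gs_pct | 100 · sclerotic/total; missing when total = 0 |
| if_pct, ta_pct | 100 · area / cortex_area; missing when medulla present |
| glomeruli_per_area, healthy_per_area, sclerotic_per_area, artery_per_area, arteriole_per_area, vessel_per_area | count / cortex_area; missing when medulla present |
| wall_lumen_ratio | wall thickness / lumen diameter |
| sub_g, sub_if, sub_ta, sub_a | Remuzzi sub-scores in {0,1,2,3} |
| total_score | sum of the four sub-scores, {0,…,12} |
| decision | single (0–3), dual (4–6), discard (≥7) |
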