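# Default item -> symptom mapping for the three emulated depression inventories.
#
# The mapping is configuration, not algorithm: it mimics the *structure* of
# clinician- and self-rated depression inventories (a 17-item HRSD-like scale
# whose items have maximum scores of 2 or 4, a 21-item BDI-like scale with
# maximum 3, and a 30-item IDS-like scale with maximum 3) without reproducing
# any copyrighted item wording. Item identifiers are synthetic. Each of the
# nine core depressive symptoms draws on items from several instruments, e.g.
# depressed mood <- 2 BDI-like + 1 HRSD-like + 1 IDS-like item.
symptoms:
  mood:
    - {instrument: bdi, item_id: bdi01, max_score: 3}
    - {instrument: bdi, item_id: bdi10, max_score: 3}
    - {instrument: hrsd, item_id: hrsd01, max_score: 4}
    - {instrument: ids, item_id: ids05, max_score: 3}
  interest:
    - {instrument: bdi, item_id: bdi04, max_score: 3}
    - {instrument: bdi, item_id: bdi12, max_score: 3}
    - {instrument: bdi, item_id: bdi21, max_score: 3}
    - {instrument: hrsd, item_id: hrsd14, max_score: 2}
    - {instrument: ids, item_id: ids19, max_score: 3}
    - {instrument: ids, item_id: ids21, max_score: 3}
    - {instrument: ids, item_id: ids22, max_score: 3}
  energy:
    - {instrument: bdi, item_id: bdi15, max_score: 3}
    - {instrument: bdi, item_id: bdi17, max_score: 3}
    - {instrument: hrsd, item_id: hrsd13, max_score: 2}
    - {instrument: ids, item_id: ids20, max_score: 3}
  guilt:
    - {instrument: bdi, item_id: bdi03, max_score: 3}
    - {instrument: bdi, item_id: bdi05, max_score: 3}
    - {instrument: hrsd, item_id: hrsd02, max_score: 4}
    - {instrument: ids, item_id: ids16, max_score: 3}
  concentration:
    - {instrument: bdi, item_id: bdi13, max_score: 3}
    - {instrument: bdi, item_id: bdi19, max_score: 3}
    - {instrument: hrsd, item_id: hrsd08, max_score: 2}
    - {instrument: ids, item_id: ids15, max_score: 3}
    - {instrument: ids, item_id: ids23, max_score: 3}
  suicidality:
    - {instrument: bdi, item_id: bdi09, max_score: 3}
    - {instrument: hrsd, item_id: hrsd03, max_score: 4}
    - {instrument: ids, item_id: ids18, max_score: 3}
  sleep:
    - {instrument: bdi, item_id: bdi16, max_score: 3}
    - {instrument: hrsd, item_id: hrsd04, max_score: 2}
    - {instrument: hrsd, item_id: hrsd05, max_score: 2}
    - {instrument: hrsd, item_id: hrsd06, max_score: 2}
    - {instrument: ids, item_id: ids01, max_score: 3}
    - {instrument: ids, item_id: ids02, max_score: 3}
    - {instrument: ids, item_id: ids03, max_score: 3}
    - {instrument: ids, item_id: ids04, max_score: 3}
  psychomotor:
    - {instrument: bdi, item_id: bdi11, max_score: 3}
    - {instrument: hrsd, item_id: hrsd09, max_score: 4}
    - {instrument: hrsd, item_id: hrsd10, max_score: 4}
    - {instrument: ids, item_id: ids24, max_score: 3}
    - {instrument: ids, item_id: ids25, max_score: 3}
  appetite:
    - {instrument: bdi, item_id: bdi18, max_score: 3}
    - {instrument: hrsd, item_id: hrsd12, max_score: 2}
    - {instrument: hrsd, item_id: hrsd16, max_score: 2}
    - {instrument: ids, item_id: ids11, max_score: 3}
    - {instrument: ids, item_id: ids12, max_score: 3}
    - {instrument: ids, item_id: ids13, max_score: 3}
    - {instrument: ids, item_id: ids14, max_score: 3}
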