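# Synthetic stand-in AOI polygons for the beach picture.
# Labels and agent/object roles follow the published 12-AOI inventory;
# vertex coordinates are NOT the study's (those were freehand and
# unpublished) but a non-overlapping grid layout on the 1680x1050
# screen, pre-buffered so no extra margin is needed by default.
picture_id: beach
regions:
- label: family_building_sandcastle
  role: active_agent
  vertices:
  - - 30
    - 30
  - - 390
    - 30
  - - 390
    - 320
  - - 30
    - 320
- label: woman_reading_book
  role: active_agent
  vertices:
  - - 450
    - 30
  - - 810
    - 30
  - - 810
    - 320
  - - 450
    - 320
- label: guitar
  role: static_object
  vertices:
  - - 870
    - 30
  - - 1230
    - 30
  - - 1230
    - 320
  - - 870
    - 320
- label: parasol
  role: static_object
  vertices:
  - - 1290
    - 30
  - - 1650
    - 30
  - - 1650
    - 320
  - - 1290
    - 320
- label: barking_dog
  role: active_agent
  vertices:
  - - 30
    - 380
  - - 390
    - 380
  - - 390
    - 670
  - - 30
    - 670
- label: couple_walking
  role: active_agent
  vertices:
  - - 450
    - 380
  - - 810
    - 380
  - - 810
    - 670
  - - 450
    - 670
- label: three_friends_playing_volleyball
  role: active_agent
  vertices:
  - - 870
    - 380
  - - 1230
    - 380
  - - 1230
    - 670
  - - 870
    - 670
- label: sea
  role: static_object
  vertices:
  - - 1290
    - 380
  - - 1650
    - 380
  - - 1650
    - 670
  - - 1290
    - 670
- label: yacht
  role: static_object
  vertices:
  - - 30
    - 730
  - - 390
    - 730
  - - 390
    - 1020
  - - 30
    - 1020
- label: seagulls
  role: active_agent
  vertices:
  - - 450
    - 730
  - - 810
    - 730
  - - 810
    - 1020
  - - 450
    - 1020
- label: condominiums
  role: static_object
  vertices:
  - - 870
    - 730
  - - 1230
    - 730
  - - 1230
    - 1020
  - - 870
    - 1020
- label: mountain
  role: static_object
  vertices:
  - - 1290
    - 730
  - - 1650
    - 730
  - - 1650
    - 1020
  - - 1290
    - 1020
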