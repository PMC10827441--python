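# Editable mapping of breed forms to canonical breeds.
# Each value is a nested list; inner lists are averaged first, then the
# result is averaged with the remaining entries (hierarchical mean).
# Names must match table breed names (case-insensitive, trimmed).
Dachshund:
  - - Dachshund (miniature long-haired)
    - Dachshund (miniature wire-haired)
  - Dachshund (standard)
Belgian shepherd:
  - - Belgian shepherd (Groenendael)
    - Belgian shepherd (Malinois)
    - Belgian shepherd (Tervueren)
Collie:
  - - Collie (rough)
    - Collie (smooth)
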