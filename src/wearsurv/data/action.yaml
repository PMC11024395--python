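# Action terms used to enrich candidate notes; matched on stems so that
# inflections ("notified", "alerts") count. Irregular inflections are handled
# by the matcher's irregular-form table.
name: action
terms:
  - alert
  - notify
  - warn
  - observe
  - identify
  - detect
  - note
  - record
  - capture
  - show
  - report
  - give
  - alarm
  - register
  - read
  - tell
  - have
  - had
  - see
  - saw
  - receive
  - get
  - got
  - notice
  - check
  - confirm
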