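{
  "style": "pattern",
  "year_pattern": "(\\d{1,4})\\s*年",
  "month_pattern": "(\\d{1,2})\\s*月",
  "day_pattern": "(\\d{1,2})\\s*日",
  "weekday_pattern": "([月火水木金土日])曜",
  "weekday_chars": {"月": 0, "火": 1, "水": 2, "木": 3, "金": 4, "土": 5, "日": 6}
}
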