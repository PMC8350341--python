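smq_id,smq_name,scope,pt_name
20000104,Synthetic GI nonspecific findings (fixture),narrow,Ileus
20000104,Synthetic GI nonspecific findings (fixture),narrow,Gastrointestinal hypomotility
20000104,Synthetic GI nonspecific findings (fixture),narrow,Gastrointestinal haemorrhage
20000104,Synthetic GI nonspecific findings (fixture),narrow,Abdominal pain
20000104,Synthetic GI nonspecific findings (fixture),narrow,Faecal impaction
20000104,Synthetic GI nonspecific findings (fixture),narrow,Intussusception
20000105,Synthetic GI obstruction (fixture),narrow,Ileus
20000105,Synthetic GI obstruction (fixture),narrow,Ileus paralytic
20000105,Synthetic GI obstruction (fixture),narrow,Subileus
20000105,Synthetic GI obstruction (fixture),narrow,Mechanical ileus
20000105,Synthetic GI obstruction (fixture),narrow,Intestinal obstruction
20000105,Synthetic GI obstruction (fixture),narrow,Large intestinal obstruction
20000105,Synthetic GI obstruction (fixture),narrow,Intestinal stenosis
20000105,Synthetic GI obstruction (fixture),narrow,Obstructive pancreatitis
20000105,Synthetic GI obstruction (fixture),narrow,Nausea
20000105,Synthetic GI obstruction (fixture),narrow,Constipation
20000107,Synthetic GI perforation (fixture),narrow,Intestinal perforation
20000107,Synthetic GI perforation (fixture),narrow,Gastrointestinal perforation
20000107,Synthetic GI perforation (fixture),narrow,Duodenal perforation
20000107,Synthetic GI perforation (fixture),narrow,Perforated ulcer
20000107,Synthetic GI perforation (fixture),narrow,Intestinal obstruction
20000107,Synthetic GI perforation (fixture),narrow,Peritonitis
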